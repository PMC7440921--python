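"""Bundled configuration presets (TOML files shipped with the package)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def preset_names() -> list[str]:
    """Names of the bundled presets (without the .toml suffix)."""
    root = resources.files(__name__)
    return sorted(
        p.name[: -len(".toml")] for p in root.iterdir() if p.name.endswith(".toml")
    )


def preset_path(name: str) -> Path:
    """Filesystem path of a bundled preset."""
    root = resources.files(__name__)
    candidate = root / f"{name}.toml"
    if not candidate.is_file():
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(preset_names())}")
    return Path(str(candidate))
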