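"""Tool configuration: cache location, offline mode, solver tolerance.

Configuration comes from a ``key = value`` text file, with command-line
flags taking precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

__all__ = ["ToolConfig"]


@dataclass
class ToolConfig:
    cache_dir: Path = Path("cache")
    offline: bool = False
    solver_tolerance: float = 1e-7
    log_path: Path = Path("curation.log")
    default_compartment: str = "c"

    def __post_init__(self) -> None:
        self.cache_dir = Path(self.cache_dir)
        self.log_path = Path(self.log_path)
        if self.solver_tolerance <= 0:
            raise ValueError("solver_tolerance must be > 0")

    @classmethod
    def from_file(cls, path) -> "ToolConfig":
        values: dict = {}
        casts = {
            "cache_dir": Path, "offline": lambda s: s.lower() in
            ("1", "true", "yes", "on"), "solver_tolerance": float,
            "log_path": Path, "default_compartment": str,
        }
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = (s.strip() for s in line.partition("="))
            if key not in casts:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = casts[key](value)
        return cls(**values)

    def override(self, **flags) -> "ToolConfig":
        """New config with any non-None flag values applied (flags win)."""
        return replace(self, **{k: v for k, v in flags.items()
                                if v is not None})

    def ensure_cache(self) -> Path:
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        return self.cache_dir
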