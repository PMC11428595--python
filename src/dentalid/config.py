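"""Key=value run configuration shared by the CLI and scripts.

A config file is plain text, one ``key = value`` per line, ``#`` comments
allowed.  Keys are the dataclass field names of
:class:`~dentalid.preprocess.PreprocessParams`,
:class:`~dentalid.registration.RegistrationParams` and the perturbation/
arch parameters of :mod:`dentalid.synthetic`; unknown keys raise.  Every
field has a default, and CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

from .preprocess import PreprocessParams
from .registration import RegistrationParams
from .synthetic import ArchParams, PerturbationParams

__all__ = ["RunConfig", "load_config", "parse_kv_text"]

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _coerce(raw: str, ftype: str):
    raw = raw.strip()
    if raw.lower() in ("none", "null", ""):
        return None
    if "bool" in ftype:
        try:
            return _BOOL[raw.lower()]
        except KeyError:
            raise ValueError(f"not a boolean: {raw!r}") from None
    if "int" in ftype and "float" not in ftype:
        return int(raw)
    if "float" in ftype:
        return float(raw)
    return raw


class RunConfig:
    """Merged preprocessing + registration + generator parameters."""

    def __init__(
        self,
        pre: PreprocessParams | None = None,
        reg: RegistrationParams | None = None,
        arch: ArchParams | None = None,
        pert: PerturbationParams | None = None,
    ) -> None:
        self.pre = pre or PreprocessParams()
        self.reg = reg or RegistrationParams()
        self.arch = arch or ArchParams()
        self.pert = pert or PerturbationParams()

    _sections = ("pre", "reg", "arch", "pert")

    def _owner(self, key: str):
        for name in self._sections:
            obj = getattr(self, name)
            for f in fields(obj):
                if f.name == key:
                    return name, f
        raise KeyError(f"unknown config key {key!r}")

    def set(self, key: str, raw_value: str) -> None:
        name, f = self._owner(key)
        value = _coerce(raw_value, str(f.type))
        setattr(self, name, replace(getattr(self, name), **{key: value}))

    def as_text(self) -> str:
        """Round-trippable echo of every parameter (provenance block)."""
        lines = []
        for name in self._sections:
            obj = getattr(self, name)
            lines.append(f"# {type(obj).__name__}")
            for f in fields(obj):
                lines.append(f"{f.name} = {getattr(obj, f.name)}")
        return "\n".join(lines) + "\n"


def parse_kv_text(text: str) -> dict[str, str]:
    out = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Config from defaults, then file, then explicit overrides."""
    cfg = RunConfig()
    if path is not None:
        for key, val in parse_kv_text(Path(path).read_text()).items():
            cfg.set(key, val)
    for key, val in (overrides or {}).items():
        if val is not None:
            cfg.set(key, str(val))
    return cfg
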