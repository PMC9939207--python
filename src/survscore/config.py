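"""Flat key-value configuration files.

Format: one ``key = value`` per line, ``#`` comments, blank lines ignored.
Values are parsed as int, float, bool (true/false), ``none``, or a
comma-separated list; anything else is kept as a string.
"""

from __future__ import annotations

from pathlib import Path

from .errors import ConfigError


def _parse_scalar(text: str):
    t = text.strip()
    low = t.lower()
    if low in {"true", "yes"}:
        return True
    if low in {"false", "no"}:
        return False
    if low in {"none", "null", ""}:
        return None
    for cast in (int, float):
        try:
            return cast(t)
        except ValueError:
            pass
    return t


def parse_value(text: str):
    if "," in text:
        return [_parse_scalar(p) for p in text.split(",")]
    return _parse_scalar(text)


def read_kv_config(path) -> dict:
    """Read a flat key-value config file into a dict."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        out[key.strip()] = parse_value(val)
    return out


def write_kv_config(path, mapping: dict) -> None:
    lines = []
    for key, val in mapping.items():
        if isinstance(val, (list, tuple)):
            val = ",".join(str(v) for v in val)
        lines.append(f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")
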