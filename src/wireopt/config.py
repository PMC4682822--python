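"""Plain-text key=value configuration files mirroring the CLI flags.

Format: one ``key = value`` pair per line; blank lines and ``#`` comments
ignored.  Values are kept as strings; the CLI coerces them where needed, and
command-line flags always override config values.
"""

from __future__ import annotations

__all__ = ["load_config"]


def load_config(path) -> dict:
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
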