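"""Plain-text key=value configuration files.

One ``key = value`` pair per line; blank lines and ``#`` comments are
ignored.  Every threshold in :class:`~somase.site_filters.FilterConfig`,
:class:`~somase.ase_calling.CallConfig` and
:class:`~somase.synthetic_cohort.SimConfig` can be set this way and
overridden per-run by a CLI flag (flag > config file > default).
"""

from __future__ import annotations

from typing import Dict

from somase.exceptions import ConfigError


def load_kv_config(path: str) -> Dict[str, str]:
    """Parse a key=value config file into a string mapping."""
    values: Dict[str, str] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            if "=" not in stripped:
                raise ConfigError(f"{path} line {line_no}: expected 'key = value'")
            key, value = stripped.split("=", 1)
            values[key.strip()] = value.strip()
    return values
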