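"""Shared delimited-file reading: header-based tab/comma sniffing.

Free-text medication fields contain spaces, so generic dialect sniffing is
unsafe; the delimiter is decided from the header line alone (tab if
present, else comma).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def sniff_sep(path: str | Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a headered CSV/TSV as strings, empty cells as ''."""
    return pd.read_csv(path, sep=sniff_sep(path), dtype=str).fillna("")
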