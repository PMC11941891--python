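"""Loaders for the plain-text data tables bundled with the package.

All numeric constants used by the toolkit (residue masses, pKa sets, the
Guruprasad dipeptide instability weights, Kyte-Doolittle hydropathy, the
default cis-element table) ship as documented TSV files under
``agpepscan/data`` so users can audit or swap them.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

WATER_MASS = 18.0153  # average mass of one water, Da


def _data_text(name: str) -> str:
    return (resources.files("agpepscan") / "data" / name).read_text()


def _rows(name: str) -> list[list[str]]:
    out = []
    for line in _data_text(name).splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        out.append(line.split("\t"))
    return out


@lru_cache(maxsize=None)
def residue_masses() -> dict[str, float]:
    """Average residue masses in Da; X maps to 0."""
    return {aa: float(m) for aa, m in _rows("residue_masses.tsv")}


@lru_cache(maxsize=None)
def kyte_doolittle() -> dict[str, float]:
    """Kyte-Doolittle hydropathy index; X maps to 0."""
    return {aa: float(v) for aa, v in _rows("kyte_doolittle.tsv")}


@lru_cache(maxsize=None)
def pka_set(name: str = "expasy") -> dict[str, float]:
    """One named pKa set as a ``group -> pKa`` map.

    Available sets: ``expasy`` (Bjellqvist convention, the default) and
    ``emboss``. Groups are ``Nterm``, ``Cterm``, and the side chains
    K, R, H, D, E, C, Y.
    """
    table: dict[str, dict[str, float]] = {}
    for set_name, group, pka in _rows("pka_sets.tsv"):
        table.setdefault(set_name, {})[group] = float(pka)
    if name not in table:
        raise KeyError(f"unknown pKa set {name!r}; available: {sorted(table)}")
    return table[name]


@lru_cache(maxsize=None)
def diwv() -> dict[str, dict[str, float]]:
    """Guruprasad dipeptide instability weight values, DIWV[first][second]."""
    rows = _rows("diwv.tsv")
    header = rows[0]
    cols = header[1:] if header[0] == "" else header
    out: dict[str, dict[str, float]] = {}
    for row in rows[1:]:
        out[row[0]] = {c: float(v) for c, v in zip(cols, row[1:])}
    return out


@lru_cache(maxsize=None)
def default_motif_rows() -> list[tuple[str, str, str]]:
    """(name, consensus, category) rows of the bundled cis-element table."""
    rows = _rows("cis_elements.tsv")
    return [tuple(r) for r in rows if r[0] != "name"]  # type: ignore[return-value]
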