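"""Signal-peptide and GPI-anchor evidence.

The real predictors (SignalP 5, big-PI, GPI-SOM) are interfaced through
their output files — they are never re-implemented here. For fully
self-contained runs the module also provides *heuristic stand-ins*:
coarse, documented hydropathy rules that let the whole pipeline execute
with zero external binaries. Their calls are labelled
``source="heuristic"`` and are no substitute for the real predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional

from ._tables import kyte_doolittle
from .seqio import ParseError, ProteinRecord


@dataclass
class SignalCall:
    protein_id: str
    is_sp: bool
    cleavage_site: Optional[int] = None  # 1-based, first residue of pair
    likelihood: Optional[float] = None
    source: str = "signalp5"


@dataclass
class GpiCall:
    protein_id: str
    is_gpi: bool
    omega_site: Optional[int] = None  # 1-based
    source: str = "bigpi"


def parse_signalp5(path: str | Path) -> list[SignalCall]:
    """Parse SignalP 5 short-format output.

    Lines starting ``#`` are comments; data lines carry the id, a
    prediction label ("SP(Sec/SPI)" or "OTHER"), probabilities, and an
    optional ``CS pos: 22-23`` field. ``is_sp`` is true iff the label
    starts with "SP"; the cleavage site is the first number of the pair.
    """
    calls: list[SignalCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: expected id and prediction")
            pid, pred = parts[0], parts[1]
            is_sp = pred.startswith("SP")
            cs = None
            lik = None
            try:
                lik = float(parts[2])
            except (IndexError, ValueError):
                pass
            for fieldtext in parts:
                if fieldtext.startswith("CS pos:"):
                    try:
                        cs = int(fieldtext.split(":")[1].strip().split("-")[0])
                    except (IndexError, ValueError):
                        raise ParseError(f"line {lineno}: malformed CS pos field")
            calls.append(SignalCall(pid, is_sp, cleavage_site=cs, likelihood=lik))
    return calls


def parse_gpi_table(
    path: str | Path, dialect: Literal["bigpi", "generic_tsv"] = "generic_tsv"
) -> list[GpiCall]:
    """Parse GPI-anchor predictions.

    ``generic_tsv``: columns id, Yes/No call, optional omega position.
    ``bigpi``: the big-PI text report — lines like
    ``query: <id> ... GPI-anchor: Yes/No [omega: <pos>]`` condensed into
    one record per protein. Duplicate ids with conflicting calls are an
    error; proteins not listed are simply absent.
    """
    calls: dict[str, GpiCall] = {}

    def add(call: GpiCall) -> None:
        prev = calls.get(call.protein_id)
        if prev is not None and prev.is_gpi != call.is_gpi:
            raise ParseError(f"conflicting GPI calls for {call.protein_id}")
        calls[call.protein_id] = call

    if dialect == "generic_tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(f"line {lineno}: expected id and call")
                pid, verdict = parts[0], parts[1].strip().lower()
                if verdict not in ("yes", "no"):
                    raise ParseError(f"line {lineno}: call must be Yes/No")
                omega = int(parts[2]) if len(parts) > 2 and parts[2].strip() else None
                add(GpiCall(pid, verdict == "yes", omega_site=omega, source="bigpi"))
    elif dialect == "bigpi":
        with open(path) as fh:
            pid = None
            for line in fh:
                line = line.strip()
                if line.lower().startswith("query:"):
                    pid = line.split(":", 1)[1].strip().split()[0]
                elif pid and "gpi-anchor" in line.lower():
                    verdict = "yes" in line.lower().split(":", 1)[1]
                    omega = None
                    if "omega:" in line.lower():
                        omega = int(line.lower().split("omega:")[1].strip(" []"))
                    add(GpiCall(pid, verdict, omega_site=omega, source="bigpi"))
                    pid = None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return list(calls.values())


def merge_gpi_calls(
    tables: Iterable[Iterable[GpiCall]], consensus: Literal["or", "and"] = "or"
) -> dict[str, bool]:
    """Combine several predictors' GPI tables into one id -> flag map.

    Default is a logical OR across predictors (a protein is GPI-anchored
    if any predictor says so); ``consensus="and"`` requires agreement of
    every table that lists the protein.
    """
    votes: dict[str, list[bool]] = {}
    for table in tables:
        for call in table:
            votes.setdefault(call.protein_id, []).append(call.is_gpi)
    op = any if consensus == "or" else all
    return {pid: op(v) for pid, v in votes.items()}


# --- heuristic stand-ins ------------------------------------------------

def _mean_hydropathy(seq: str) -> float:
    kd = kyte_doolittle()
    return sum(kd.get(c, 0.0) for c in seq) / len(seq)


def heuristic_signal_peptide(seq: str) -> SignalCall:
    """Coarse signal-peptide call from hydropathy alone.

    Positive iff (a) residues 1-5 contain a K or R (the n-region's
    positive charge) and (b) somewhere within residues 1-30 there is a
    window of >= 8 consecutive residues with mean Kyte-Doolittle
    hydropathy > 1.6 (the h-region core). A stand-in for testing, not a
    SignalP replacement. Requires length >= 15.
    """
    if len(seq) < 15:
        raise ValueError("sequence too short for a signal peptide call (< 15)")
    has_basic = any(c in "KR" for c in seq[:5])
    head = seq[:30]
    core_at = None
    for w in range(8, len(head) + 1):
        for i in range(len(head) - w + 1):
            if _mean_hydropathy(head[i : i + w]) > 1.6:
                core_at = i + 1
                break
        if core_at:
            break
    is_sp = has_basic and core_at is not None
    return SignalCall("", is_sp, cleavage_site=None, source="heuristic")


def heuristic_gpi(seq: str) -> GpiCall:
    """Coarse GPI-anchor call from the C-terminal hydrophobic tail.

    Positive iff the final 15 residues have mean Kyte-Doolittle
    hydropathy > 1.0 and a small residue (G/A/S/N/D/C — the candidate
    omega site) occurs 18-28 positions from the C-terminus. Requires
    length >= 30.
    """
    if len(seq) < 30:
        raise ValueError("sequence too short for a GPI call (< 30)")
    tail_ok = _mean_hydropathy(seq[-15:]) > 1.0
    omega = None
    for k in range(18, 29):  # k residues from the C-terminus
        if seq[-k] in "GASNDC":
            omega = len(seq) - k + 1
            break
    return GpiCall("", tail_ok and omega is not None,
                   omega_site=omega if tail_ok else None, source="heuristic")


def heuristic_calls(
    proteome: Iterable[ProteinRecord],
) -> tuple[dict[str, bool], dict[str, bool]]:
    """Run both heuristics over a proteome -> (sp_map, gpi_map).

    Sequences too short for a heuristic are called negative.
    """
    sp_map: dict[str, bool] = {}
    gpi_map: dict[str, bool] = {}
    for rec in proteome:
        try:
            sp_map[rec.id] = heuristic_signal_peptide(rec.seq).is_sp
        except ValueError:
            sp_map[rec.id] = False
        try:
            gpi_map[rec.id] = heuristic_gpi(rec.seq).is_gpi
        except ValueError:
            gpi_map[rec.id] = False
    return sp_map, gpi_map


def calls_to_map(calls: Iterable[SignalCall]) -> dict[str, bool]:
    return {c.protein_id: c.is_sp for c in calls}
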