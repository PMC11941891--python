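"""The AG-peptide identification screen.

Arabinogalactan (AG) peptides are classical arabinogalactan proteins with
a very short backbone: an N-terminal signal peptide, a proline/alanine/
serine/threonine (PAST)-rich core that is O-glycosylated on its Ser/Thr
and hydroxyproline residues, and often a C-terminal GPI-anchor addition
sequence. Because hydroxyproline is a post-translational state, Pro
stands proxy for it in the translated sequence; the screen therefore
looks for

1. a backbone length in a fixed window (default 50-75 aa),
2. a PAST composition bias of at least ``past_min_pct`` (default 35%),
3. signal-peptide (and optionally GPI) evidence from external predictors,
4. at least ``min_repeat_total`` AP/PA/SP/TP dipeptide repeats, and
5. the absence of any other annotated protein domain.

All threshold comparisons are inclusive, and PAST% is computed on the
full primary sequence, initiator Met and signal peptide included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

from .seqio import ProteinRecord

PAST_RESIDUES = frozenset("PAST")
REPEAT_PAIRS = ("AP", "PA", "SP", "TP")


@dataclass
class ScreenParams:
    """Thresholds and flags controlling the screen.

    The defaults implement the standard AG-peptide definition; the
    ``relaxed_length`` preset (50-90 aa) matches the broader definition
    used in some of the AGP literature.
    """

    min_len: int = 50
    max_len: int = 75
    past_min_pct: float = 35.0
    require_sp: bool = True
    require_gpi: bool = False
    min_repeat_total: int = 1
    domain_allowlist: frozenset[str] = frozenset()
    missing_policy: str = "negative"  # or "error"

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")
        if not (0 <= self.past_min_pct <= 100):
            raise ValueError("past_min_pct must be in [0, 100]")

    @classmethod
    def relaxed_length(cls, **kw) -> "ScreenParams":
        kw.setdefault("max_len", 90)
        return cls(**kw)

    @classmethod
    def strict_repeats(cls, **kw) -> "ScreenParams":
        kw.setdefault("min_repeat_total", 2)
        return cls(**kw)


@dataclass
class CandidateRow:
    """One screened protein — mirrors a row of the final report."""

    protein: ProteinRecord
    past_pct: float
    sp: bool = False
    gpi: bool = False
    repeats: tuple[int, int, int, int] = (0, 0, 0, 0)
    name: Optional[str] = None
    locus_id: Optional[str] = None
    physchem: Optional[object] = None

    @property
    def aa_size(self) -> int:
        return len(self.protein.seq)

    @property
    def repeat_total(self) -> int:
        return sum(self.repeats)


def past_fraction(seq: str) -> float:
    """PAST percentage of a sequence: 100 * (#P+#A+#S+#T) / length.

    Computed on the full primary sequence. The exact value is returned;
    reports round it half-up to two decimals.
    """
    if not seq:
        raise ValueError("empty sequence")
    n = sum(1 for c in seq if c in PAST_RESIDUES)
    return 100.0 * n / len(seq)


def past_pct_2dp(seq: str) -> float:
    """PAST percentage rounded half-up to 2 decimals (report convention)."""
    return float(Decimal(repr(past_fraction(seq))).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))


def count_dipeptide_repeats(seq: str) -> tuple[int, int, int, int]:
    """Count AP, PA, SP and TP dipeptides, overlapping occurrences included.

    Every adjacent residue pair is classified, so "APA" contributes one
    AP and one PA. These pairs are the translated-sequence proxies of the
    Ala-Hyp, Ser-Hyp and Thr-Hyp glycosylation motifs of AG peptides.
    """
    if not seq:
        raise ValueError("empty sequence")
    counts = dict.fromkeys(REPEAT_PAIRS, 0)
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair in counts:
            counts[pair] += 1
    return tuple(counts[p] for p in REPEAT_PAIRS)  # type: ignore[return-value]


def length_past_filter(
    proteome: Iterable[ProteinRecord], params: ScreenParams | None = None
) -> list[ProteinRecord]:
    """Keep proteins inside the length window with PAST% >= threshold.

    Both comparisons are inclusive and the PAST comparison uses the
    unrounded fraction. Input order is preserved.
    """
    params = params or ScreenParams()
    return [
        p
        for p in proteome
        if params.min_len <= len(p.seq) <= params.max_len
        and past_fraction(p.seq) >= params.past_min_pct
    ]


def apply_evidence(
    candidates: Iterable[ProteinRecord],
    sp_calls: Mapping[str, bool],
    gpi_calls: Mapping[str, bool],
    params: ScreenParams | None = None,
) -> list[CandidateRow]:
    """Join signal-peptide / GPI predictor evidence onto candidates.

    Candidates failing ``require_sp`` / ``require_gpi`` are dropped;
    survivors carry the evidence flags verbatim for reporting. Ids absent
    from a call map are treated as negative with a warning under the
    default ``missing_policy``; ``"error"`` raises instead.
    """
    params = params or ScreenParams()
    rows: list[CandidateRow] = []
    missing_ids: list[str] = []
    for p in candidates:
        for calls in (sp_calls, gpi_calls):
            if p.id not in calls:
                missing_ids.append(p.id)
        sp = bool(sp_calls.get(p.id, False))
        gpi = bool(gpi_calls.get(p.id, False))
        if params.require_sp and not sp:
            continue
        if params.require_gpi and not gpi:
            continue
        rows.append(
            CandidateRow(
                protein=p,
                past_pct=past_pct_2dp(p.seq),
                sp=sp,
                gpi=gpi,
                repeats=count_dipeptide_repeats(p.seq),
            )
        )
    if missing_ids:
        uniq = sorted(set(missing_ids))
        if params.missing_policy == "error":
            raise KeyError(f"no predictor call for: {', '.join(uniq)}")
        warnings.warn(
            f"{len(uniq)} candidate(s) without predictor calls treated as "
            f"negative: {', '.join(uniq[:5])}{'...' if len(uniq) > 5 else ''}"
        )
    return rows


def apply_repeat_and_domain_exclusion(
    rows: Iterable[CandidateRow],
    domains: Mapping[str, set[str]] | None = None,
    params: ScreenParams | None = None,
) -> list[CandidateRow]:
    """Drop rows with too few dipeptide repeats or a disallowed domain.

    A row is excluded when its AP+PA+SP+TP total is below
    ``min_repeat_total`` or when it carries any annotated domain not in
    ``domain_allowlist`` (an empty allowlist means any domain excludes).
    An empty/missing domain map excludes nothing.
    """
    params = params or ScreenParams()
    domains = domains or {}
    out = []
    for r in rows:
        if r.repeat_total < params.min_repeat_total:
            continue
        extra = set(domains.get(r.protein.id, set())) - set(params.domain_allowlist)
        if extra:
            continue
        out.append(r)
    return out


def run_screen(
    proteome: Iterable[ProteinRecord],
    sp_calls: Mapping[str, bool],
    gpi_calls: Mapping[str, bool],
    domains: Mapping[str, set[str]] | None = None,
    params: ScreenParams | None = None,
) -> list[CandidateRow]:
    """Full screen: length/PAST filter, evidence join, repeat/domain exclusion."""
    params = params or ScreenParams()
    kept = length_past_filter(proteome, params)
    rows = apply_evidence(kept, sp_calls, gpi_calls, params)
    return apply_repeat_and_domain_exclusion(rows, domains, params)
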