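"""End-to-end identification workflow with stage-count logging.

Wires the modules into the funnel: length/PAST filter -> signal-peptide /
GPI evidence join -> repeat & domain exclusion -> physicochemical
profiling -> (optional) chromosome-order naming. Deterministic given a
config; each stage's survivor count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import annot, genomics, physchem, screen, seqio

logger = logging.getLogger("agpepscan")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one identification run depends on."""

    proteome: str
    signalp: Optional[str] = None
    gpi_tables: list[str] = field(default_factory=list)
    gpi_consensus: str = "or"
    domains: Optional[str] = None
    gff3: Optional[str] = None
    id_map: Optional[str] = None  # TSV protein id -> locus id
    params: screen.ScreenParams = field(default_factory=screen.ScreenParams)
    pka: str = "expasy"
    name_prefix: str = "OsAGP"
    name_suffix: str = "P"
    use_heuristics: bool = False  # stand-in predictors when no tables given

    def header(self) -> str:
        p = self.params
        return (
            f"agpepscan run: min_len={p.min_len} max_len={p.max_len} "
            f"past_min={p.past_min_pct} require_sp={p.require_sp} "
            f"require_gpi={p.require_gpi} min_repeats={p.min_repeat_total} "
            f"pka_set={self.pka} "
            f"sp_source={'heuristic' if self.use_heuristics and not self.signalp else 'signalp5'}"
        )


def _read_domains(path: str) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            out.setdefault(parts[0], set()).update(p for p in parts[1:] if p)
    return out


def _read_id_map(path: str) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 2:
                out[parts[0]] = parts[1]
    return out


def run_pipeline(config: RunConfig) -> list[screen.CandidateRow]:
    """Run the identification funnel; returns the surviving rows."""
    try:
        proteome = seqio.read_fasta(config.proteome, alphabet="protein", lenient=True)
    except (OSError, seqio.ParseError) as e:
        raise PipelineError("read_proteome", str(e))
    logger.info("input proteins: %d", len(proteome))

    params = config.params
    kept = screen.length_past_filter(proteome, params)
    logger.info("after length/PAST filter: %d", len(kept))

    try:
        if config.signalp:
            sp_map = annot.calls_to_map(annot.parse_signalp5(config.signalp))
        elif config.use_heuristics:
            sp_map, _ = annot.heuristic_calls(kept)
        else:
            sp_map = {}
        if config.gpi_tables:
            tables = [
                annot.parse_gpi_table(p, dialect="generic_tsv")
                for p in config.gpi_tables
            ]
            gpi_map = annot.merge_gpi_calls(tables, consensus=config.gpi_consensus)
        elif config.use_heuristics:
            _, gpi_map = annot.heuristic_calls(kept)
        else:
            gpi_map = {}
    except (OSError, seqio.ParseError) as e:
        raise PipelineError("read_evidence", str(e))

    rows = screen.apply_evidence(kept, sp_map, gpi_map, params)
    logger.info("after evidence join: %d", len(rows))

    domains = _read_domains(config.domains) if config.domains else {}
    rows = screen.apply_repeat_and_domain_exclusion(rows, domains, params)
    logger.info("after repeat/domain exclusion: %d", len(rows))

    for r in rows:
        r.physchem = physchem.profile(r.protein.seq, pka=config.pka)

    if config.gff3:
        try:
            genes = seqio.read_gff3(config.gff3)
        except (OSError, seqio.ParseError) as e:
            raise PipelineError("read_gff3", str(e))
        surviving_ids = {r.protein.id for r in rows}
        names = genomics.assign_family_names(
            [g for g in genes if g.gene_id in surviving_ids],
            prefix=config.name_prefix,
            suffix=config.name_suffix,
        )
        for r in rows:
            r.name = names.get(r.protein.id)

    if config.id_map:
        id_map = _read_id_map(config.id_map)
        for r in rows:
            r.locus_id = id_map.get(r.protein.id)

    return rows


def write_report(
    rows: list[screen.CandidateRow], path: str | Path, config: RunConfig
) -> None:
    seqio.write_report_tsv(rows, path, header_comment=config.header())
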