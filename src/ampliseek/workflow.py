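"""Pipeline orchestration: demultiplex -> trim -> assemble -> support filter
-> homology screen -> precursor annotation -> physicochemical profiling.

Every stage writes a TSV report; per-stage counters are conserved (reads in
= kept + discarded) and collected in a machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import amplicon_pipeline as ap
from . import homology_screen as hs
from . import precursor_annotation as pa
from . import physchem as pc
from .seqcore import NucSeq, PepSeq, QualRead, find_orfs, longest_orf

__all__ = ["PipelineConfig", "PipelineReport", "ConfigError", "StageError",
           "run_pipeline", "annotate_contig"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters, defaulting to the published thresholds."""

    window_len: int = 20
    max_polymorphic: int = 3
    identity_threshold: float = 0.8
    trim_limit: float = 0.05
    min_read_length: int = 100
    min_support: int = 3
    alpha: float = 0.05
    cover_novel: float = 70.0
    platform_max: int = 450
    barcode_length: int = 10
    barcode_max_mismatch: int = 1
    min_overlap: int = 50
    min_overlap_identity: float = 0.95
    polymorphism_floor: float = 0.2
    flag_threshold: float = 0.02
    stringent_identity: float = 0.99
    signal_length: int = 22
    strip_amidation: bool = True
    adapters: tuple[str, ...] = ()
    barcodes: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 < self.trim_limit < 1, "trim_limit must be in (0, 1)"),
            (self.min_read_length >= 1, "min_read_length must be >= 1"),
            (self.min_support >= 1, "min_support must be >= 1"),
            (0 < self.alpha <= 1, "alpha must be in (0, 1]"),
            (0 < self.identity_threshold <= 1, "identity_threshold in (0, 1]"),
            (0 <= self.cover_novel <= 100, "cover_novel must be a percentage"),
            (0 < self.min_overlap_identity <= 1, "min_overlap_identity in (0, 1]"),
            (self.platform_max > 0, "platform_max must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        object.__setattr__(self, "adapters", tuple(self.adapters))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["adapters"] = list(data["adapters"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PeptideCall:
    contig_id: str
    annotation: pa.PrecursorAnnotation
    mature: PepSeq
    tier: pa.NoveltyTier
    class_assignment: pa.ClassAssignment
    profile: pc.PhyschemProfile
    ranabox: bool


@dataclass
class PipelineReport:
    counts: dict
    contigs: list
    hits: list
    peptides: list

    def summary_rows(self) -> list[dict]:
        return [self.counts]


def annotate_contig(
    contig: NucSeq,
    cfg: PipelineConfig,
) -> pa.PrecursorAnnotation | None:
    """Call the precursor ORF on a contig and split it.

    Candidate ORFs (Met-initiated, >= 10 aa) are ranked by precursor
    plausibility before length: a dibasic cleavage site, a terminating stop
    codon, an acidic-or-neutral propeptide and a non-anionic mature region.
    Pure longest-ORF calling mistakes chance UTR/poly-A ORFs (which read as
    lysine runs) for the precursor on amplicon contigs.
    """
    from .physchem import net_charge

    best: tuple | None = None
    for cand in find_orfs(contig, require_start=True, min_aa=10):
        ann = pa.split_precursor(
            PepSeq(contig.id, cand.protein.sequence),
            signal_length=cfg.signal_length,
            strip_amidation=cfg.strip_amidation,
        )
        if ann.no_cleavage_site:
            continue
        pro = ann.propeptide.sequence
        mat = ann.mature.sequence
        score = (
            cand.protein.residues.endswith("*"),
            pro != "X" and net_charge(pro) <= 0,
            mat not in ("", "X") and net_charge(mat) >= 0,
            len(cand.protein),
        )
        if best is None or score > best[0]:
            ann.orf = cand
            best = (score, ann)
    return best[1] if best is not None else None


def run_pipeline(
    reads: list[QualRead],
    db: list[PepSeq],
    cfg: PipelineConfig,
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Execute the full pipeline on in-memory reads against a known-AMP
    database; optionally write per-stage TSV reports under ``outdir``."""
    counts: dict = {"raw_reads": len(reads)}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # -- demultiplex ---------------------------------------------------
    try:
        if cfg.barcodes:
            bins = ap.demultiplex(reads, dict(cfg.barcodes), cfg.barcode_max_mismatch)
            counts["undetermined_reads"] = len(bins.pop("undetermined"))
            pooled = [r for sample in bins.values() for r in sample]
        else:
            pooled = list(reads)
            counts["undetermined_reads"] = 0
    except Exception as exc:  # noqa: BLE001
        raise StageError("demultiplex", exc) from exc

    # -- trim ----------------------------------------------------------
    try:
        trim_cfg = ap.TrimConfig(
            error_prob_limit=cfg.trim_limit,
            min_length=cfg.min_read_length,
            adapters=cfg.adapters,
            barcode_length=cfg.barcode_length,
            barcode_max_mismatch=cfg.barcode_max_mismatch,
        )
        trimmed = []
        for r in pooled:
            t = ap.trim_read(r, trim_cfg)
            if t is not None:
                trimmed.append(t)
        counts["trimmed_reads"] = len(trimmed)
        counts["discarded_reads"] = len(pooled) - len(trimmed)
    except Exception as exc:  # noqa: BLE001
        raise StageError("trim", exc) from exc

    # -- assemble + support filter + remap ------------------------------
    try:
        read_seqs = [NucSeq(r.id, r.bases) for r in trimmed]
        contigs = ap.assemble_olc(
            read_seqs,
            min_overlap=cfg.min_overlap,
            min_overlap_identity=cfg.min_overlap_identity,
        )
        counts["contigs_assembled"] = len(contigs)
        contigs = ap.filter_support(contigs, cfg.min_support)
        counts["contigs_supported"] = len(contigs)
        if contigs:
            remap = ap.remap_and_flag(
                contigs,
                read_seqs,
                polymorphism_floor=cfg.polymorphism_floor,
                flag_threshold=cfg.flag_threshold,
                stringent_identity=cfg.stringent_identity,
                min_overlap=cfg.min_overlap,
            )
            contigs = ap.filter_support(remap.contigs, cfg.min_support)
            counts["contigs_flagged"] = len(remap.flagged)
        else:
            counts["contigs_flagged"] = 0
        counts["contigs_final"] = len(contigs)
    except Exception as exc:  # noqa: BLE001
        raise StageError("assemble", exc) from exc

    # -- homology screen -----------------------------------------------
    try:
        if contigs and db:
            hits = hs.translated_search(
                [c.consensus for c in contigs], db, alpha=cfg.alpha
            )
        else:
            hits = []
        counts["amps_on_target"] = len(hits)
    except Exception as exc:  # noqa: BLE001
        raise StageError("screen", exc) from exc

    # -- annotate + physchem -------------------------------------------
    try:
        positive = {h.query_id for h in hits}
        peptides: list[PeptideCall] = []
        for contig in contigs:
            if contig.consensus.id not in positive:
                continue
            ann = annotate_contig(contig.consensus, cfg)
            if ann is None:
                logger.info("contig %s: no annotatable precursor ORF",
                            contig.consensus.id)
                continue
            mature = ann.mature
            if not mature.sequence or mature.sequence == "X":
                continue
            pep_hits = hs.protein_search(mature, db)
            tier = pa.assign_novelty(mature, pep_hits, alpha=cfg.alpha,
                                     cover_novel=cfg.cover_novel)
            box, _ = pa.detect_ranabox(mature)
            peptides.append(
                PeptideCall(
                    contig_id=contig.consensus.id,
                    annotation=ann,
                    mature=mature,
                    tier=tier,
                    class_assignment=pa.classify(mature),
                    profile=pc.profile_peptide(mature),
                    ranabox=box,
                )
            )
        counts["peptides_called"] = len(peptides)
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotate", exc) from exc

    report = PipelineReport(counts=counts, contigs=contigs, hits=hits,
                            peptides=peptides)
    if out is not None:
        _write_reports(out, report, cfg)
    return report


def _write_reports(out: Path, report: PipelineReport, cfg: PipelineConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    with open(out / "summary.json", "w") as fh:
        json.dump(report.counts, fh, indent=2)
    with open(out / "contigs.tsv", "w") as fh:
        fh.write("contig\tlength\tsupport\tpolymorphism_rate\n")
        for c in report.contigs:
            fh.write(
                f"{c.consensus.id}\t{len(c)}\t{c.supporting_reads}\t"
                f"{c.polymorphism_rate:.4f}\n"
            )
    from .seqcore import write_fasta, write_peptides

    write_fasta(out / "contigs.fasta", [c.consensus for c in report.contigs])
    hs.write_hits_tsv(out / "hits.tsv", report.hits)
    with open(out / "peptides.tsv", "w") as fh:
        fh.write(
            "contig\tsequence\tlength\tcharge\tH\tMW\tamidated\tranabox\t"
            "class\ttier\tbest_hit\tidentity\tcoverage\n"
        )
        for p in report.peptides:
            hit = p.tier.supporting_hit
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        p.contig_id, p.mature.sequence, p.profile.length,
                        f"{p.profile.net_charge:+d}",
                        f"{p.profile.mean_hydrophobicity:.3f}",
                        f"{p.profile.molecular_weight:.1f}",
                        p.mature.amidated, p.ranabox,
                        p.class_assignment.label, p.tier.tier.value,
                        hit.subject_id if hit else ".",
                        f"{hit.identity:.1f}" if hit else ".",
                        f"{hit.coverage:.1f}" if hit else ".",
                    )
                )
                + "\n"
            )
    write_peptides(out / "mature_peptides.fasta", [p.mature for p in report.peptides])
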