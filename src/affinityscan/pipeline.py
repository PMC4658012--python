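"""End-to-end orchestration of the score -> evaluate / model workflows.

Both pipelines write every intermediate ScoreMatrix to disk so runs are
resumable and each stage independently inspectable, and every output file
gets a JSON provenance sidecar (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import affinityscan
from affinityscan.affinity import CutoffGrid, score_matrix
from affinityscan.binding import auc_table, cutoff_sweep, filter_uninformative, mean_auc_per_predictor
from affinityscan.expression import (
    crossval_r2,
    fit_lasso,
    fit_linear,
    normalize_expression,
    shuffled_pwm_control,
)
from affinityscan.pwm import PWM, Background, background_from_fasta, read_pwm_counts, read_pwm_probs
from affinityscan.regions import (
    extract_sequences,
    promoter_from_tss,
    read_segmentation,
    read_state_map,
    read_tss_table,
    refine_with_chromatin,
)

logger = logging.getLogger("affinityscan")


@dataclass
class RunConfig:
    """Paths and knobs for a pipeline run; validated before any compute."""

    out_dir: Path
    pwm_dir: Path | None = None
    pwm_format: str = "counts"  # "counts" (JASPAR PFM) or "probs"
    bg_path: Path | None = None
    pos_fasta: Path | None = None
    neg_fasta: Path | None = None
    tss_path: Path | None = None
    genome_path: Path | None = None
    chromhmm_path: Path | None = None
    statemap_path: Path | None = None
    expr_path: Path | None = None
    cutoffs: CutoffGrid = field(default_factory=CutoffGrid)
    occupancy_cutoff: float = 0.8
    up: int = 1500
    down: int = 500
    seed: int = 0
    lasso: bool = False
    shuffle_control: bool = False
    cv_folds: int = 10

    def validate(self) -> None:
        for name in ("pwm_dir", "bg_path", "pos_fasta", "neg_fasta", "tss_path",
                     "genome_path", "chromhmm_path", "statemap_path", "expr_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        self.out_dir = Path(self.out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in vars(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def write_provenance(cfg: RunConfig, path: Path) -> None:
    sidecar = Path(str(path) + ".provenance.json")
    sidecar.write_text(
        json.dumps(
            {"config_hash": cfg.config_hash(), "seed": cfg.seed, "version": affinityscan.__version__},
            indent=2,
        )
        + "\n"
    )


def load_pwms(pwm_dir: Path, pwm_format: str = "counts") -> list[PWM]:
    reader = read_pwm_counts if pwm_format == "counts" else read_pwm_probs
    paths = sorted(p for p in Path(pwm_dir).iterdir() if p.suffix in (".pfm", ".txt", ".tsv", ".jaspar"))
    if not paths:
        raise FileNotFoundError(f"no PWM files (*.pfm, *.txt, *.tsv, *.jaspar) in {pwm_dir}")
    return [reader(p) for p in paths]


def load_background(bg_path: Path | None) -> Background:
    if bg_path is None:
        return Background()
    text = Path(bg_path).read_text()
    if text.lstrip().startswith(">"):
        return background_from_fasta(bg_path)
    freqs = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        base, value = line.split("\t")
        freqs[base.upper()] = float(value)
    return Background(freqs=[freqs[b] for b in "ACGT"])


def read_fasta_records(path: Path):
    from affinityscan.affinity import SequenceRecord

    records = []
    current_id, chunks = None, []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if current_id is not None:
                records.append(SequenceRecord(id=current_id, bases="".join(chunks)))
            current_id = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if current_id is not None:
        records.append(SequenceRecord(id=current_id, bases="".join(chunks)))
    return records


def build_regions(cfg: RunConfig):
    """TSS table (+ optional segmentation) -> extracted promoter sequences."""
    import pyfaidx

    tss_records = read_tss_table(cfg.tss_path)
    regions = [promoter_from_tss(t, cfg.up, cfg.down) for t in tss_records]
    if cfg.chromhmm_path is not None:
        state_map = read_state_map(cfg.statemap_path) if cfg.statemap_path else None
        segments = read_segmentation(cfg.chromhmm_path, state_map)
        regions = [refine_with_chromatin(r, segments) for r in regions]
        closed = [r.gene_id for r in regions if r.fully_closed]
        if closed:
            logger.info("dropped %d fully-closed regions: %s", len(closed), ", ".join(closed[:10]))
    genome = pyfaidx.Fasta(str(cfg.genome_path))
    return regions, extract_sequences(regions, genome)


def run_binding_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Positives/negatives FASTA -> per-predictor AUC sweep reports."""
    cfg.validate()
    pwms = load_pwms(cfg.pwm_dir, cfg.pwm_format)
    bg = load_background(cfg.bg_path)
    positives = read_fasta_records(cfg.pos_fasta)
    negatives = read_fasta_records(cfg.neg_fasta)
    logger.info("binding eval: %d PWMs, %d positives, %d negatives", len(pwms), len(positives), len(negatives))

    for mode, cutoff, stem in [("tba", None, "scores_tba")] + [
        ("occupancy", c, f"scores_occupancy_{c:g}") for c in cfg.cutoffs
    ]:
        for label, seqs in (("pos", positives), ("neg", negatives)):
            sm = score_matrix(pwms, seqs, bg, mode=mode, cutoff=cutoff)
            path = cfg.out_dir / f"{stem}_{label}.tsv"
            sm.to_tsv(path)
            write_provenance(cfg, path)

    records = cutoff_sweep(pwms, {"run": (positives, negatives)}, cfg.cutoffs, bg)
    kept, dropped = filter_uninformative(records)
    logger.info("dropped %d uninformative (experiment, PWM) pairs", dropped)

    outputs = {}
    long_path = cfg.out_dir / "auc_records.tsv"
    auc_table(kept).to_csv(long_path, sep="\t", index=False)
    write_provenance(cfg, long_path)
    outputs["auc_records"] = long_path
    wide_path = cfg.out_dir / "auc_per_pwm.tsv"
    mean_auc_per_predictor(kept).to_csv(wide_path, sep="\t")
    write_provenance(cfg, wide_path)
    outputs["auc_per_pwm"] = wide_path
    return outputs


def run_expression_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Regions (+/- chromatin) -> TBA and occupancy designs -> model reports."""
    cfg.validate()
    pwms = load_pwms(cfg.pwm_dir, cfg.pwm_format)
    bg = load_background(cfg.bg_path)
    regions, seqs = build_regions(cfg)
    logger.info("expression model: %d PWMs, %d regions (%d scorable)", len(pwms), len(regions), len(seqs))

    raw_expr = pd.read_csv(cfg.expr_path, sep="\t", index_col=0)
    expr = normalize_expression(raw_expr)

    designs = {
        "tba": score_matrix(pwms, seqs, bg, mode="tba"),
        f"occupancy_{cfg.occupancy_cutoff:g}": score_matrix(
            pwms, seqs, bg, mode="occupancy", cutoff=cfg.occupancy_cutoff
        ),
    }
    outputs: dict[str, Path] = {}
    summary: dict[str, dict] = {}
    for name, design in designs.items():
        dpath = cfg.out_dir / f"design_{name}.tsv"
        design.to_tsv(dpath)
        write_provenance(cfg, dpath)
        outputs[f"design_{name}"] = dpath
        for col in expr.columns:
            key = f"{name}/{col}"
            try:
                fit = fit_linear(design, expr[col])
            except ValueError as exc:
                # e.g. an occupancy design where most genes have no passing
                # site (-inf) leaves too few usable genes for this model
                logger.warning("model %s not fit: %s", key, exc)
                summary[key] = {"error": str(exc)}
                continue
            entry = fit.summary_dict()
            entry["cv_r2"] = crossval_r2(design, expr[col], folds=cfg.cv_folds, seed=cfg.seed)
            if cfg.lasso and name == "tba":
                lasso = fit_lasso(design, expr[col], seed=cfg.seed, folds=cfg.cv_folds)
                entry["lasso_cv_r2"] = lasso.cv_r2
                entry["lasso_n_selected"] = len(lasso.selected)
                entry["lasso_penalty"] = lasso.penalty
            summary[key] = entry
            coef_path = cfg.out_dir / f"coefficients_{name}_{col}.tsv"
            coef = pd.DataFrame({"coefficient": fit.coefficients, "p": fit.coef_p_values})
            coef.to_csv(coef_path, sep="\t", index_label="pwm")
            write_provenance(cfg, coef_path)

    if cfg.shuffle_control:
        table, p = shuffled_pwm_control(pwms, seqs, expr, bg, seed=cfg.seed)
        ctrl_path = cfg.out_dir / "shuffled_control.tsv"
        table.to_csv(ctrl_path, sep="\t")
        write_provenance(cfg, ctrl_path)
        outputs["shuffled_control"] = ctrl_path
        summary["shuffled_control_wilcoxon_p"] = p

    summary_path = cfg.out_dir / "fit_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=float) + "\n")
    write_provenance(cfg, summary_path)
    outputs["fit_summary"] = summary_path
    return outputs
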