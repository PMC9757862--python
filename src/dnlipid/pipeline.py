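"""One-command orchestration: simulate → process → analyze → report.

``run_all`` executes the stages in order and writes a reproducible report
bundle: the per-mille lipid matrix, the filter provenance log, the discovery
table (t, p, sPLS-DA rank, relevance), the two regression grids, a volcano
plot, a run manifest (package version, seed, thresholds) and a structured
JSON-lines log. In simulate mode everything derives from the configured seed,
so two runs of the same config produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .cohort_stats import DnlPanel, discover, run_table_suites
from .masslist import MassList, mass_lists_from_config, load_masslist_config
from .processing import (
    DEFAULT_MIN_PRESENCE,
    DEFAULT_MIN_SNR,
    DEFAULT_QC_R,
    DEFAULT_TOL_PPM,
    process_peaklists,
    read_peaklists,
    read_qc_manifest,
    write_peaklist_csv,
)
logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and mode for one pipeline run."""

    out_dir: str | Path = "dnl_out"
    mode: str = "simulate"  # "simulate" | "real"
    seed: int | None = 0
    n_subjects: int = 867
    # real-mode inputs
    peaklists_dir: str | Path | None = None
    masslist_file: str | Path | None = None
    qc_manifest: str | Path | None = None
    cohort_file: str | Path | None = None
    # thresholds
    tol_ppm: float = DEFAULT_TOL_PPM
    min_snr: float = DEFAULT_MIN_SNR
    min_presence: float = DEFAULT_MIN_PRESENCE
    qc_r: float = DEFAULT_QC_R
    anthropometric_alpha: float = 0.05
    panel: tuple[str, ...] = ()
    make_plots: bool = True

    def validate(self) -> None:
        for name in ("tol_ppm", "min_snr", "qc_r"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"threshold {name} must be positive")
        if not (0 < self.min_presence <= 1):
            raise ValueError("min_presence must be in (0, 1]")
        if self.mode not in ("simulate", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.seed is None:
            raise ValueError("simulate mode requires a seed")
        if self.mode == "real":
            for name in ("peaklists_dir", "cohort_file"):
                if getattr(self, name) is None:
                    raise ValueError(f"real mode requires {name}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


class _RunLog:
    """Structured stage/event log written as JSON lines (no wall-clock, so
    simulate-mode bundles are byte-identical under a fixed seed)."""

    def __init__(self) -> None:
        self.events: list[dict] = []

    def log(self, stage: str, event: str, **counts) -> None:
        entry = {"stage": stage, "event": event, **counts}
        self.events.append(entry)
        logger.info("%s: %s %s", stage, event, counts or "")

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report bundle in memory.

    Any stage failure aborts with a stage-named RuntimeError and leaves no
    partial downstream outputs.
    """
    from . import synthetic as syn  # local import to keep module load light

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runlog = _RunLog()
    bundle: dict = {}

    stage = "simulate" if config.mode == "simulate" else "ingest"
    try:
        if config.mode == "simulate":
            params = syn.GeneratorParams(
                n_subjects=config.n_subjects, seed=int(config.seed)
            )
            cohort = syn.generate_cohort(params)
            cohort_df = syn.cohort_to_frame(cohort)
            truth = syn.generate_lipid_profiles(cohort, params)
            masslists = syn.simulation_mass_list(truth.columns)
            samples, qcs = syn.render_spectra(truth, masslists, params)
            peaklists = samples + qcs
            runlog.log(stage, "simulated", subjects=len(cohort),
                       species=truth.shape[1], qc_spectra=len(qcs))
        else:
            pl_dir = Path(config.peaklists_dir)
            paths = sorted(
                p for p in pl_dir.iterdir()
                if p.suffix.lower() in (".csv", ".mzml")
            )
            if config.qc_manifest is None:
                raise ValueError(
                    "QC manifest is required in real mode (the linearity "
                    "filter cannot run without dilution factors)"
                )
            qc_map = read_qc_manifest(config.qc_manifest)
            peaklists = read_peaklists(paths, qc_manifest=qc_map)
            if config.masslist_file:
                pos = MassList.from_tsv(config.masslist_file, "positive")
                neg = MassList.from_tsv(config.masslist_file, "negative")
                masslists = {"positive": pos, "negative": neg}
            else:
                masslists = mass_lists_from_config()
            cohort_df = pd.read_csv(config.cohort_file, index_col=0)
            runlog.log(stage, "ingested", peaklists=len(peaklists))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "process"
    try:
        matrix = process_peaklists(
            peaklists,
            masslists,
            tol_ppm=config.tol_ppm,
            min_snr=config.min_snr,
            min_presence=config.min_presence,
            qc_r=config.qc_r,
        )
        runlog.log(
            stage, "matrix_built",
            samples=matrix.values.shape[0], variables=matrix.values.shape[1],
            removed=sum(1 for e in matrix.filter_log if e["decision"] == "removed"),
        )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "analyze"
    try:
        common = matrix.values.index.intersection(cohort_df.index)
        labels = cohort_df.loc[common, "gdm"].astype(bool)
        discovery = discover(matrix.values.loc[common], labels)
        panel = DnlPanel(config.panel) if config.panel else DnlPanel()
        tables = run_table_suites(matrix, cohort_df, panel)
        runlog.log(
            stage, "analyzed",
            relevant=int(discovery["relevant"].sum()),
            maternal_rows=len(tables["maternal"]),
            neonatal_rows=len(tables["neonatal"]),
        )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "report"
    try:
        _write_tsv(matrix.values, out / "lipid_matrix.tsv", index=True)
        _write_tsv(matrix.filter_log_frame(), out / "filter_log.tsv")
        _write_tsv(discovery.reset_index(), out / "discovery.tsv")
        _write_tsv(tables["maternal"], out / "maternal_grid.tsv")
        _write_tsv(tables["neonatal"], out / "neonatal_grid.tsv")
        manifest = {
            "package": "dnlipid",
            "version": __version__,
            "mode": config.mode,
            "seed": config.seed,
            "n_subjects": config.n_subjects if config.mode == "simulate" else None,
            "thresholds": {
                "tol_ppm": config.tol_ppm,
                "min_snr": config.min_snr,
                "min_presence": config.min_presence,
                "qc_r": config.qc_r,
            },
            "lipidomic_p_threshold": float(discovery.attrs.get("p_threshold", 0.0)),
            "anthropometric_alpha": config.anthropometric_alpha,
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        if config.make_plots:
            plot_volcano(discovery, out / "volcano.png")
        runlog.write(out / "run_log.jsonl")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    bundle.update(
        matrix=matrix, discovery=discovery, tables=tables,
        cohort=cohort_df, manifest=manifest, out_dir=out,
    )
    return bundle


def plot_volcano(discovery: pd.DataFrame, path: str | Path) -> None:
    """Basic volcano plot: group-difference t statistic vs −log10 p."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    thr = discovery.attrs.get("p_threshold", 0.002)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    logp = -np.log10(discovery["p"].clip(lower=1e-300))
    colors = np.where(discovery.get("relevant", False), "tab:blue", "0.7")
    ax.scatter(discovery["t"], logp, s=12, c=colors)
    ax.axhline(-np.log10(thr), ls="--", lw=0.8, c="k")
    ax.set_xlabel("t statistic (GDM vs euglycemic)")
    ax.set_ylabel("-log10 p")
    ax.set_title("Lipid species group comparison")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def make_fixtures(size: str, seed: int, out_dir: str | Path) -> Path:
    """Write a self-contained fixture directory (peak lists, QC manifest,
    cohort CSV, mass-list TSV).

    ``tiny``: 12 subjects + 3 QCs + a compact ~20-entry mass list (seconds;
    unit-test scale). ``demo``: 867 subjects matching the study's group
    sizes (documentation scale).
    """
    from . import synthetic as syn

    if size not in ("tiny", "demo"):
        raise ValueError(f"unknown fixture size {size!r}")
    out = Path(out_dir)
    (out / "peaklists").mkdir(parents=True, exist_ok=True)
    if size == "tiny":
        params = syn.GeneratorParams(
            n_subjects=12,
            seed=seed,
            background_species=syn.DEFAULT_BACKGROUND_SPECIES[:11],
            n_decoy_peaks=30,
        )
    else:
        params = syn.GeneratorParams(n_subjects=867, seed=seed)
    cohort = syn.generate_cohort(params)
    cohort_df = syn.cohort_to_frame(cohort)
    truth = syn.generate_lipid_profiles(cohort, params)
    masslists = syn.simulation_mass_list(truth.columns)
    samples, qcs = syn.render_spectra(truth, masslists, params)
    suffix = {"positive": "pos", "negative": "neg"}
    qc_rows = []
    for pl in samples + qcs:
        write_peaklist_csv(
            pl, out / "peaklists" / f"{pl.sample_id}_{suffix[pl.polarity]}.csv"
        )
        if pl.is_qc:
            qc_rows.append({"sample_id": pl.sample_id, "dilution": pl.qc_dilution})
    pd.DataFrame(qc_rows).drop_duplicates().to_csv(
        out / "qc_manifest.csv", index=False
    )
    cohort_df.to_csv(out / "cohort.csv")
    with open(out / "masslist.tsv", "w") as fh:
        fh.write("mz\tspecies_name\tadduct\tpolarity\tformula\n")
        for pol in sorted(masslists):
            for e in masslists[pol]:
                fh.write(
                    f"{e.mz:.6f}\t{e.species.name}\t{e.adduct.label}\t"
                    f"{e.adduct.polarity}\t{e.species.molecular_formula().hill()}\n"
                )
    return out
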