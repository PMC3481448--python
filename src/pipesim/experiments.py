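"""End-to-end pipeline runs and parameter sweeps.

``run_once`` composes the full simulation — proteome subsampling, ground
truth generation, digestion, signal and noise, MS1/MS2 detection, roll-up
and high-level analysis — deterministically for a given seed. ``run_sweep``
repeats it over a parameter grid with replicate runs and aggregates the
performance indices, mirroring how the simulator is used to map out the
working range of instrument and design parameters.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance_model as am
from . import analysis as an
from . import detection as det
from . import rollup as ru
from . import signal_model as sm
from ._rng import stage_rng, subseed
from .abundance_model import AbundanceConfig
from .analysis import AnalysisConfig, RunResult
from .detection import DetectionConfig
from .proteome import ProteomeCatalog, digest, generate_synthetic_proteome, read_fasta
from .rollup import RollupConfig
from .signal_model import SignalConfig

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ExperimentPlan",
    "SweepSummary",
    "run_once",
    "run_sweep",
    "summarize_medians",
    "with_overrides",
    "DEFAULT_SWEEPS",
]


@dataclass
class PipelineConfig:
    """Full configuration of one simulated experiment (defaults: Table-style)."""

    abundance: AbundanceConfig = field(default_factory=AbundanceConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    rollup: RollupConfig = field(default_factory=RollupConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    # digestion
    missed_cleavages: int = 0
    min_pep_length: int = 6
    max_pep_length: int = 40
    # proteome source (used when run_once is not handed a catalog)
    fasta_path: str | None = None
    n_proteome: int = 1000
    length_law: tuple[float, float] = (350.0, 100.0)
    proteome_seed: int = 12345


# Flat parameter names accepted by ``with_overrides`` and sweep plans,
# mapped onto the nested configuration.
_SCALAR_PARAMS = {
    "t": ("abundance", "t"),
    "theta": ("abundance", "theta"),
    "M": ("abundance", "M"),
    "n_markers": ("abundance", "n_markers"),
    "n_background": ("abundance", "n_background"),
    "rho": ("abundance", "rho"),
    "D": ("abundance", "D"),
    "phi": ("abundance", "phi"),
    "marker_quantile_cap": ("abundance", "marker_quantile_cap"),
    "kappa": ("signal", "kappa"),
    "sat": ("signal", "sat"),
    "alpha": ("signal", "alpha"),
    "beta": ("signal", "beta"),
    "k": ("detection", "k"),
    "p": ("detection", "p"),
    "b": ("detection", "b"),
    "overlap_aware": ("detection", "overlap_aware"),
    "mass_resolution": ("detection", "mass_resolution"),
    "n_scans": ("detection", "n_scans"),
    "rt_tol_frac": ("detection", "rt_tol_frac"),
    "n_ms2_replicates": ("detection", "n_ms2_replicates"),
    "identifiability_model": ("detection", "identifiability_model"),
    "perfect_detection": ("detection", "perfect_detection"),
    "max_missing_rate": ("rollup", "max_missing_rate"),
    "min_corr": ("rollup", "min_corr"),
    "min_peptides": ("rollup", "min_peptides"),
    "alpha_level": ("analysis", "alpha_level"),
    "n_features": ("analysis", "n_features"),
    "knn_k": ("analysis", "knn_k"),
    "n_test_per_class": ("analysis", "n_test_per_class"),
}


def with_overrides(config: PipelineConfig, **params) -> PipelineConfig:
    """Copy ``config`` with flat-named parameter overrides applied.

    Besides the scalar names, understands ``e_lo``/``e_hi`` (efficiency
    bounds), ``a_lo``/``a_hi`` (fold-change bounds) and ``alpha_with_beta_120x``
    (sets α to the value and β = 120α, the coupled noise sweep).
    """
    cfg = copy.deepcopy(config)
    for name, value in params.items():
        if name in _SCALAR_PARAMS:
            section, fld = _SCALAR_PARAMS[name]
            setattr(cfg, section, replace(getattr(cfg, section), **{fld: value}))
        elif name == "e_lo":
            cfg.signal = replace(cfg.signal, e_range=(value, cfg.signal.e_range[1]))
        elif name == "e_hi":
            cfg.signal = replace(cfg.signal, e_range=(cfg.signal.e_range[0], value))
        elif name == "a_lo":
            cfg.abundance = replace(
                cfg.abundance, a_range=(value, cfg.abundance.a_range[1])
            )
        elif name == "a_hi":
            cfg.abundance = replace(
                cfg.abundance, a_range=(cfg.abundance.a_range[0], value)
            )
        elif name == "alpha_with_beta_120x":
            cfg.signal = replace(cfg.signal, alpha=value, beta=120.0 * value)
        elif hasattr(cfg, name):
            setattr(cfg, name, value)
        else:
            raise KeyError(f"unknown parameter {name!r}")
    return cfg


def _load_proteome(config: PipelineConfig) -> ProteomeCatalog:
    if config.fasta_path is not None:
        return read_fasta(config.fasta_path)
    return generate_synthetic_proteome(
        config.n_proteome, config.length_law, seed=config.proteome_seed
    )


def _subsample_interleaved(
    catalog: ProteomeCatalog, config: PipelineConfig, seed: int
) -> tuple[ProteomeCatalog, list[str]]:
    """Random background + marker proteins, markers placed at block starts.

    With block size D, row order is [marker, D−1 background] per marker block
    followed by the remaining background, so every marker's correlation-block
    partners are background proteins.
    """
    ab = config.abundance
    n_sel = ab.n_markers + ab.n_background
    if n_sel > catalog.n_pro:
        raise ValueError(
            f"cannot select {n_sel} proteins from a proteome of {catalog.n_pro}"
        )
    rng = stage_rng(seed, "protein_subsample")
    chosen = rng.choice(catalog.n_pro, size=n_sel, replace=False)
    ids = [catalog.proteins[i].id for i in chosen]
    markers, background = ids[: ab.n_markers], ids[ab.n_markers:]
    order: list[str] = []
    bg_iter = iter(background)
    D = ab.D
    for m in markers:
        order.append(m)
        for _ in range(D - 1):
            nxt = next(bg_iter, None)
            if nxt is None:
                break
            order.append(nxt)
    order.extend(bg_iter)
    return catalog.subset(order), markers


def _marker_indices(protein_ids: list[str], marker_ids: list[str]) -> np.ndarray:
    idx = {pid: i for i, pid in enumerate(protein_ids)}
    return np.array([idx[m] for m in marker_ids], dtype=int)


def _observe(
    dig: ProteomeCatalog,
    truth: am.GroundTruthSamples,
    config: PipelineConfig,
    efficiency: np.ndarray,
    p_i: np.ndarray,
    overlap: np.ndarray,
    noise_seed: int,
    det_seed: int,
    ms2_seed: int,
) -> det.ObservedPeptideTable:
    """Signal + noise + detection for one set of samples."""
    c_pep = sm.rollup_protein_to_peptide(dig, truth)
    mu = sm.expected_abundance(
        c_pep, efficiency, config.signal.kappa, config.signal.sat
    )
    v = sm.add_noise(mu, config.signal.alpha, config.signal.beta, noise_seed)
    snr_m = det.snr(mu, config.signal.alpha, config.signal.beta)
    tpr_m = det.tpr(snr_m, overlap, config.detection)
    detected = det.detect_ms1(tpr_m, det_seed)
    identified = det.identify_ms2(
        p_i, truth.concentrations.shape[1], config.detection.n_ms2_replicates,
        ms2_seed,
    )
    return det.link(detected, identified, v, p_i, overlap)


def run_once(
    config: PipelineConfig, seed: int, catalog: ProteomeCatalog | None = None
) -> RunResult:
    """One full pipeline realisation; bit-reproducible for a given seed."""
    if catalog is None:
        catalog = _load_proteome(config)
    sub, marker_ids = _subsample_interleaved(catalog, config, subseed(seed, "subsample"))
    dig = digest(
        sub,
        missed_cleavages=config.missed_cleavages,
        min_length=config.min_pep_length,
        max_length=config.max_pep_length,
        n_scans=config.detection.n_scans,
    )
    protein_ids = [p.id for p in dig.proteins]
    m_idx = _marker_indices(protein_ids, marker_ids)
    ab = config.abundance

    eta = am.draw_control_means(
        ab, len(protein_ids), subseed(seed, "eta"), marker_indices=m_idx
    )
    fold = am.draw_fold_changes(ab, len(protein_ids), m_idx, subseed(seed, "fold"))
    truth = am.draw_samples(
        ab, eta, fold, marker_ids, protein_ids, subseed(seed, "train_samples")
    )

    efficiency = sm.draw_efficiencies(
        dig, config.signal.e_range, subseed(seed, "efficiency")
    )
    p_i = det.assign_identifiability(dig, config.detection, subseed(seed, "ident"))
    overlap = det.overlap_counts(
        dig,
        config.detection.mass_resolution,
        config.detection.n_scans,
        config.detection.rt_tol_frac,
    )

    table = _observe(
        dig, truth, config, efficiency, p_i, overlap,
        subseed(seed, "train_noise"),
        subseed(seed, "train_ms1"),
        subseed(seed, "train_ms2"),
    )

    survivors, audit = ru.filter_peptides(table, dig, config.rollup)
    estimate = ru.estimate_protein(
        table, survivors, dig, config.signal.kappa, config.rollup.min_peptides
    )
    estimate.filter_audit = audit

    qerr = ru.quantification_error(truth, estimate)
    pep_missing, pro_missing = ru.missing_value_rates(table, estimate)
    peptide_id_rate = float(table.observed.any(axis=1).mean())
    protein_quant_rate = float(estimate.quantified.mean())
    pct_markers = an.detect_markers(
        estimate, truth.class_labels, marker_ids, config.analysis
    )

    # Independent test samples from the same generative model, pushed through
    # the same pipeline realisation (same e_i, p_i, overlap; fresh noise and
    # detection draws), then rolled up with the training-derived survivor sets.
    test_truth = am.draw_samples(
        ab, eta, fold, marker_ids, protein_ids,
        subseed(seed, "test_samples"), M=config.analysis.n_test_per_class,
    )
    test_table = _observe(
        dig, test_truth, config, efficiency, p_i, overlap,
        subseed(seed, "test_noise"),
        subseed(seed, "test_ms1"),
        subseed(seed, "test_ms2"),
    )
    test_estimate = ru.estimate_protein(
        test_table, survivors, dig, config.signal.kappa, config.rollup.min_peptides
    )

    n_feat = config.analysis.n_features
    feats_obs = an.select_features(estimate.conc_hat, truth.class_labels, n_feat)
    err_knn_obs, err_lda_obs = an.train_and_test_classifiers(
        estimate.conc_hat[feats_obs].T,
        truth.class_labels,
        test_estimate.conc_hat[feats_obs].T,
        test_truth.class_labels,
        config.analysis,
    )
    feats_orig = an.select_features(truth.concentrations, truth.class_labels, n_feat)
    err_knn_orig, err_lda_orig = an.train_and_test_classifiers(
        truth.concentrations[feats_orig].T,
        truth.class_labels,
        test_truth.concentrations[feats_orig].T,
        test_truth.class_labels,
        config.analysis,
    )

    return RunResult(
        peptide_id_rate=peptide_id_rate,
        protein_quant_rate=protein_quant_rate,
        qerr=qerr,
        pct_markers_detected=pct_markers,
        peptide_missing_rate=pep_missing,
        protein_missing_rate=pro_missing,
        err_lda_observed=err_lda_obs,
        err_knn_observed=err_knn_obs,
        err_lda_original=err_lda_orig,
        err_knn_original=err_knn_orig,
    )


@dataclass
class ExperimentPlan:
    """A one-parameter sweep with replicate runs per grid value."""

    base_config: PipelineConfig
    sweep_param: str
    sweep_values: list
    n_runs: int = 50
    seed_base: int = 0
    catalog: ProteomeCatalog | None = None

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        # fail early on unknown parameter names
        with_overrides(self.base_config, **{self.sweep_param: self.sweep_values[0]})


@dataclass
class SweepSummary:
    """Long-format per-run results plus per-setting aggregates."""

    runs: pd.DataFrame        # columns: sweep value, run, every RunResult index
    aggregates: pd.DataFrame  # per setting: mean / median / sd of each index
    sweep_param: str

    def to_tsv(self, runs_path, agg_path) -> None:
        self.runs.to_csv(runs_path, sep="\t", index=False)
        self.aggregates.to_csv(agg_path, sep="\t")


def run_sweep(plan: ExperimentPlan) -> SweepSummary:
    """Execute the sweep: for each grid value, ``n_runs`` seeded replicates."""
    catalog = (
        plan.catalog if plan.catalog is not None else _load_proteome(plan.base_config)
    )
    rows = []
    n_failed = 0
    for value in plan.sweep_values:
        cfg = with_overrides(plan.base_config, **{plan.sweep_param: value})
        for r in range(plan.n_runs):
            seed = plan.seed_base + r
            try:
                res = run_once(cfg, seed, catalog=catalog)
            except Exception:
                logger.exception(
                    "run failed (%s=%r, run %d); excluded", plan.sweep_param, value, r
                )
                n_failed += 1
                continue
            rows.append({plan.sweep_param: value, "run": r, **res.to_dict()})
    if n_failed:
        logger.warning("%d run(s) failed and were excluded", n_failed)
    runs = pd.DataFrame(rows)
    indices = [c for c in runs.columns if c not in (plan.sweep_param, "run")]
    aggregates = runs.groupby(plan.sweep_param)[indices].agg(
        ["mean", "median", "std"]
    )
    return SweepSummary(runs=runs, aggregates=aggregates, sweep_param=plan.sweep_param)


def summarize_medians(results: list[RunResult]) -> dict[str, float]:
    """Per-index median across a collection of runs."""
    if not results:
        raise ValueError("no results to summarise")
    df = pd.DataFrame([r.to_dict() for r in results])
    return {k: float(v) for k, v in df.median().items()}


# Sweep grids mirroring the simulator's standard experiments. Endpoints not
# dictated by the model are package choices.
DEFAULT_SWEEPS: dict[str, list] = {
    "e_lo": [0.1, 0.3, 0.5, 0.7, 0.9],
    "kappa": [0.1, 1.0, 10.0, 100.0, 1e3, 1e4, 1e5],
    "M": [30, 50, 70, 90, 110],
    "alpha_with_beta_120x": [0.01, 0.02, 0.04, 0.08, 0.16],
    "mass_resolution": [500, 1000, 5000, 10000, 50000],
    "n_ms2_replicates": [1, 2, 3, 4, 5, 6],
}


def write_run_result(result: RunResult, out_dir) -> None:
    """Serialise a RunResult as JSON and a one-row TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = result.to_dict()
    (out / "run_result.json").write_text(json.dumps(d, indent=2) + "\n")
    pd.DataFrame([d]).to_csv(out / "run_result.tsv", sep="\t", index=False)
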