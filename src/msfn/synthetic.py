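"""Synthetic three-view survival cohorts with known ground truth.

The generator emulates the shape of a multi-omics breast-cancer cohort:
a clinical view of mixed discrete/continuous covariates, a continuous
expression view, a quantile-discretized copy-number view, and censored
survival follow-up whose 5-year outcome is the classification target.

Informative columns carry a class-conditional Gaussian mean shift; a
configurable fraction of that signal is driven by a latent factor shared
across views, so cross-view correlation (what the similarity-network
branch exploits) can be dialed independently of per-view signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import OmicsBlock, SurvivalTable

#: Months in the survival threshold separating long- from short-term survivors.
THRESHOLD_MONTHS = 60.0

_DEFAULT_FEATURES = {"clinical": 33, "expression": 60, "cnv": 40}
_DEFAULT_INFORMATIVE = {"clinical": 6, "expression": 12, "cnv": 10}
_DEFAULT_SIGNAL = {"clinical": 2.0, "expression": 2.0, "cnv": 2.0}
_N_CLINICAL_DISCRETE = 24  # of the 33 clinical covariates, mirroring a mixed panel


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its stated ranges."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``signal_strength`` is the between-class mean shift (in noise SDs) on
    informative columns; ``cross_view_redundancy`` is the fraction of the
    informative-signal variance shared across views through a common latent
    factor.
    """

    n_patients: int = 200
    n_features: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_FEATURES))
    signal_strength: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SIGNAL))
    n_informative: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_INFORMATIVE))
    cross_view_redundancy: float = 0.4
    class_balance: float = 0.25
    missing_frac: float = 0.05
    censor_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("need at least 2 patients")
        for view in self.n_features:
            if self.n_informative.get(view, 0) > self.n_features[view]:
                raise ConfigurationError(
                    f"{view}: n_informative exceeds n_features"
                )
            if self.signal_strength.get(view, 0.0) < 0:
                raise ConfigurationError(f"{view}: signal_strength must be >= 0")
        if not 0.0 <= self.cross_view_redundancy <= 1.0:
            raise ConfigurationError("cross_view_redundancy must be in [0, 1]")
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigurationError("class_balance must be in (0, 1)")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ConfigurationError("missing_frac must be in [0, 1)")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigurationError("censor_rate must be in [0, 1)")


@dataclass
class SyntheticCohort:
    views: dict[str, OmicsBlock]
    survival: SurvivalTable
    true_label: np.ndarray

    @property
    def patient_ids(self) -> np.ndarray:
        return self.survival.patient_ids


def _quantile_discretize(column: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Map a continuous column onto ``levels`` by equal-probability quantiles."""
    edges = np.quantile(column, np.linspace(0, 1, len(levels) + 1)[1:-1])
    return levels[np.searchsorted(edges, column, side="left")].astype(float)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort; bit-identical for a fixed ``config.seed``.

    Informative columns are class-conditional Gaussians with mean
    ``±signal/2`` (difference = ``signal_strength``); the remaining columns
    are standard-normal noise. The copy-number view is discretized to
    {-2,-1,0,1,2} by column quintiles after signal injection. Survival times
    are exponential within class, rejection-sampled so that true long-term
    survivors (label 1) live past 60 months and short-term survivors die
    before 60 months; independent uniform censoring then overwrites a
    fraction of follow-ups so the loader's exclusion rule is exercised.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = np.array([f"P{i:04d}" for i in range(n)], dtype=object)

    n_pos = int(round(config.class_balance * n))
    n_pos = min(max(n_pos, 1), n - 1)
    label = np.zeros(n, dtype=int)
    label[rng.permutation(n)[:n_pos]] = 1

    shared = rng.standard_normal(n)  # latent factor common to all views
    r = config.cross_view_redundancy

    views: dict[str, OmicsBlock] = {}
    for view in sorted(config.n_features):
        f = config.n_features[view]
        k_inf = config.n_informative.get(view, 0)
        signal = config.signal_strength.get(view, 0.0)
        x = rng.standard_normal((n, f))
        if k_inf:
            shift = np.where(label == 1, signal / 2.0, -signal / 2.0)
            mix = np.sqrt(r) * shared[:, None] + np.sqrt(1.0 - r) * x[:, :k_inf]
            x[:, :k_inf] = shift[:, None] + mix
        names = np.array([f"{view}_f{j:04d}" for j in range(f)], dtype=object)
        kinds = None
        if view == "cnv":
            levels = np.array([-2, -1, 0, 1, 2])
            for j in range(f):
                x[:, j] = _quantile_discretize(x[:, j], levels)
        elif view == "clinical":
            n_disc = min(_N_CLINICAL_DISCRETE, f)
            disc_cols = rng.permutation(f)[:n_disc]
            kinds = np.array(["continuous"] * f, dtype=object)
            kinds[disc_cols] = "discrete"
            levels = np.array([0, 1, 2, 3])
            for j in disc_cols:
                x[:, j] = _quantile_discretize(x[:, j], levels)
        block = OmicsBlock(
            values=x, patient_ids=ids, feature_names=names,
            view_kind=view if view in ("clinical", "expression", "cnv") else "expression",
            feature_kinds=kinds,
        )
        views[view] = block

    # Survival: exponential within class, rejection-sampled at the threshold.
    time = np.empty(n)
    event = np.ones(n, dtype=int)
    for i in range(n):
        if label[i] == 1:
            t = rng.exponential(THRESHOLD_MONTHS)
            while t <= THRESHOLD_MONTHS:
                t = rng.exponential(THRESHOLD_MONTHS)
        else:
            t = rng.exponential(THRESHOLD_MONTHS / 2.0)
            while t >= THRESHOLD_MONTHS:
                t = rng.exponential(THRESHOLD_MONTHS / 2.0)
        time[i] = t
    censored = rng.random(n) < config.censor_rate
    for i in np.flatnonzero(censored):
        time[i] = rng.uniform(0.0, time[i])
        event[i] = 0
    time = np.maximum(time, 1e-3)

    if config.missing_frac > 0 and "clinical" in views:
        views["clinical"] = inject_missingness(
            views["clinical"], config.missing_frac, seed=int(rng.integers(2**31))
        )

    surv = SurvivalTable(patient_ids=ids, time_months=time, event=event)
    return SyntheticCohort(views=views, survival=surv, true_label=label)


def inject_missingness(block: OmicsBlock, frac: float, seed: int) -> OmicsBlock:
    """Mark exactly ``round(frac * n_cells)`` entries as missing (NaN)."""
    if not 0.0 <= frac < 1.0:
        raise ConfigurationError("missing fraction must be in [0, 1)")
    n_cells = block.values.size
    n_missing = int(round(frac * n_cells))
    values = block.values.copy()
    if n_missing:
        rng = np.random.default_rng(seed)
        flat = rng.choice(n_cells, size=n_missing, replace=False)
        values.flat[flat] = np.nan
    return block.with_values(values)


def write_cohort(cohort: SyntheticCohort, out_dir: str) -> dict[str, str]:
    """Write each view and the survival table as TSV; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    for view, block in cohort.views.items():
        df = pd.DataFrame(block.values, columns=block.feature_names)
        df.insert(0, "patient_id", block.patient_ids)
        path = os.path.join(out_dir, f"{view}.tsv")
        df.to_csv(path, sep="\t", index=False)
        paths[view] = path
    surv = pd.DataFrame(
        {
            "patient_id": cohort.survival.patient_ids,
            "time_months": cohort.survival.time_months,
            "event": cohort.survival.event,
        }
    )
    path = os.path.join(out_dir, "survival.tsv")
    surv.to_csv(path, sep="\t", index=False)
    paths["survival"] = path
    return paths
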