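"""Weighted linear least-squares fitting of PIP models, with energy
ceilings, train/test splits, and the standard precision metrics.

The fit minimizes sum_i w_i (V(x_i) - E_i)^2 over the linear coefficients of
either model type, solved by SVD with truncation of small singular values.
Inverse-energy weights w = eps/(eps + dE), dE the energy above the set
minimum in hartree, emphasize the low-energy region; weighting defaults on
for fragmented models and off for many-body models.  Gradients are never fit
targets; gradient metrics compare analytic model gradients against stored
reference gradients on a seeded subsample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from . import units
from .chemio import DatasetFile


@dataclass
class FitConfig:
    weight_epsilon: float = 0.02          # hartree
    use_weights: bool | None = None       # None: on for fragmented, off for MB
    split_fraction: float = 0.8
    svd_rcond: float = 1e-10
    seed: int = 0
    energy_ceiling_cm: float | None = 80_000.0
    gradient_sample_size: int | None = None

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.weight_epsilon <= 0:
            raise ValueError("weight_epsilon must be positive")


@dataclass
class FitReport:
    """Energy metrics in cm^-1; gradient metrics in cm^-1/bohr."""

    eRMSE_train: float
    eRMSE_test: float | None
    eWRMSE_train: float
    eMAE_train: float
    r2_train: float
    gRMSE: float | None
    gMAE: float | None
    n_data: int
    n_coeff: int
    rank: int

    def summary(self) -> str:
        lines = [f"n_data {self.n_data}   n_coeff {self.n_coeff}   "
                 f"rank {self.rank}",
                 f"eRMSE train  {self.eRMSE_train:10.3f} cm-1"]
        if self.eRMSE_test is not None:
            lines.append(f"eRMSE test   {self.eRMSE_test:10.3f} cm-1")
        lines += [f"eWRMSE train {self.eWRMSE_train:10.3f} cm-1",
                  f"eMAE train   {self.eMAE_train:10.3f} cm-1",
                  f"R2 train     {self.r2_train:12.6f}"]
        if self.gRMSE is not None:
            lines += [f"gRMSE        {self.gRMSE:10.3f} cm-1/bohr",
                      f"gMAE         {self.gMAE:10.3f} cm-1/bohr"]
        return "\n".join(lines)


def apply_ceiling(dataset: DatasetFile, ceiling_cm: float):
    """Keep frames with E - E_min <= ceiling (cm^-1); returns
    (filtered dataset, kept, dropped)."""
    e = dataset.energies()
    rel = (e - e.min()) * units.CM_PER_HARTREE
    keep = rel <= ceiling_cm
    kept = [g for g, k in zip(dataset.geometries, keep) if k]
    if not kept:
        raise ValueError("energy ceiling excludes every frame")
    out = DatasetFile(kept, dialect=dataset.dialect,
                      ceiling_applied_cm=ceiling_cm)
    return out, int(keep.sum()), int((~keep).sum())


def weights(energies_hartree: np.ndarray, epsilon: float) -> np.ndarray:
    """Inverse-energy weights eps/(eps + dE), dE relative to the minimum."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    e = np.asarray(energies_hartree, float)
    return epsilon / (epsilon + (e - e.min()))


def solve(features: np.ndarray, targets: np.ndarray,
          sample_weights: np.ndarray | None = None, rcond: float = 1e-10):
    """Truncated-SVD weighted least squares.

    Rows are scaled by sqrt(w) (identical to weighted normal equations);
    singular values below rcond * sigma_max are discarded.  Returns
    (coefficients, diagnostics dict with rank/singular_values/residual).
    """
    F = np.asarray(features, float)
    t = np.asarray(targets, float)
    if F.shape[0] < F.shape[1]:
        raise ValueError(f"underdetermined system: {F.shape[0]} rows for "
                         f"{F.shape[1]} coefficients")
    if sample_weights is not None:
        sw = np.sqrt(np.asarray(sample_weights, float))
        F = F * sw[:, None]
        t = t * sw
    coef, residual, rank, sv = np.linalg.lstsq(F, t, rcond=rcond)
    if rank == 0:
        raise ValueError("feature matrix has rank 0")
    return coef, {"rank": int(rank), "singular_values": sv,
                  "residual": float(residual[0]) if residual.size else None}


def split_indices(n: int, train_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = int(round(train_fraction * n))
    return np.sort(perm[:k]), np.sort(perm[k:])


def fit_model(model, dataset: DatasetFile, config: FitConfig | None = None):
    """Fit a model's coefficients to a labeled dataset.

    Returns (fitted model, FitReport).  The model is not mutated; a copy
    carrying the coefficients is returned.
    """
    config = config or FitConfig()
    if config.energy_ceiling_cm is not None:
        dataset, _, _ = apply_ceiling(dataset, config.energy_ceiling_cm)
    geoms = dataset.geometries
    e = dataset.energies()
    F = model.feature_matrix(geoms)
    use_w = config.use_weights
    if use_w is None:
        use_w = model.kind == "fragmented"
    w = weights(e, config.weight_epsilon) if use_w else None

    tr, te = split_indices(len(geoms), config.split_fraction, config.seed)
    coef, diag = solve(F[tr], e[tr], None if w is None else w[tr],
                       rcond=config.svd_rcond)
    fitted = _with_coefficients(model, coef)
    report = metrics(fitted, dataset, features=F, train_idx=tr, test_idx=te,
                     weight_epsilon=config.weight_epsilon,
                     gradient_sample_size=config.gradient_sample_size,
                     seed=config.seed, rank=diag["rank"])
    return fitted, report


def _with_coefficients(model, coef):
    fitted = dc_replace(model) if hasattr(model, "__dataclass_fields__") else model
    fitted.coefficients = np.asarray(coef, float)
    return fitted


def metrics(model, dataset: DatasetFile, features=None, train_idx=None,
            test_idx=None, weight_epsilon: float = 0.02,
            gradient_sample_size: int | None = None, seed: int = 0,
            rank: int | None = None) -> FitReport:
    """Precision metrics of a fitted model against a labeled dataset."""
    geoms = dataset.geometries
    e = dataset.energies()
    if features is None:
        features = model.feature_matrix(geoms)
    pred = features @ model.coefficients
    if train_idx is None:
        train_idx = np.arange(len(geoms))
    res = pred - e
    cm = units.CM_PER_HARTREE
    w = weights(e, weight_epsilon)
    rtr = res[train_idx]
    e_rmse = float(np.sqrt(np.mean(rtr ** 2)) * cm)
    e_wrmse = float(np.sqrt(np.sum(w[train_idx] * rtr ** 2)
                            / np.sum(w[train_idx])) * cm)
    e_mae = float(np.mean(np.abs(rtr)) * cm)
    etr = e[train_idx]
    ss_res = float(np.sum(rtr ** 2))
    ss_tot = float(np.sum((etr - etr.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    e_rmse_test = (float(np.sqrt(np.mean(res[test_idx] ** 2)) * cm)
                   if test_idx is not None and len(test_idx) else None)

    g_rmse = g_mae = None
    if gradient_sample_size:
        if any(g.gradient is None for g in geoms):
            raise ValueError("gradient metrics requested but the dataset "
                             "carries no reference gradients")
        rng = np.random.default_rng(seed)
        size = min(gradient_sample_size, len(geoms))
        sample = rng.choice(len(geoms), size=size, replace=False)
        diffs = []
        for i in sample:
            diffs.append(model.gradient(geoms[i]) - geoms[i].gradient)
        d = np.concatenate(diffs)
        g_rmse = float(np.sqrt(np.mean(d ** 2)) * cm)
        g_mae = float(np.mean(np.abs(d)) * cm)

    return FitReport(eRMSE_train=e_rmse, eRMSE_test=e_rmse_test,
                     eWRMSE_train=e_wrmse, eMAE_train=e_mae, r2_train=r2,
                     gRMSE=g_rmse, gMAE=g_mae, n_data=len(geoms),
                     n_coeff=len(model.coefficients),
                     rank=rank if rank is not None else len(model.coefficients))
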