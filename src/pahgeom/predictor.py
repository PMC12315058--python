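"""Fixed-coefficient isomerization-energy predictor.

Applies the published three-descriptor linear model (trained on the C36H20
isomer subset) or any FitResult to descriptor values, reporting a symmetric
error bound equal to the model's training MAD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorSet
from .modeling import ErrorStats, FitResult

__all__ = [
    "PublishedModel",
    "PUBLISHED_MODEL",
    "predict_published",
    "predict",
]

#: training MAD (kcal/mol) of the combined three-descriptor model over the
#: full isomer set, used as the default symmetric error bound.
DEFAULT_BOUND = 2.48


@dataclass(frozen=True)
class PublishedModel:
    """The published fixed-coefficient model (immutable).

    delta_E = 0.0207 * sum_dihedral - 339.00 * homa + 16.44 * theta_rmsd + 236.09
    """

    sum_dihedral_coef: float = 0.0207  # kcal/mol per degree
    homa_coef: float = -339.00  # kcal/mol
    theta_rmsd_coef: float = 16.44  # kcal/mol per degree
    intercept: float = 236.09  # kcal/mol
    bound: float = DEFAULT_BOUND  # kcal/mol, training MAD
    provenance: str = "trained on the C36H20 isomer subset (1182 geometries)"

    def as_fit_result(self) -> FitResult:
        """The same model as a FitResult (stats hold only the bound MAD)."""
        return FitResult(
            descriptor_names=("sum_dihedral", "homa", "theta_rmsd"),
            coefficients=np.array(
                [self.sum_dihedral_coef, self.homa_coef, self.theta_rmsd_coef]
            ),
            intercept=self.intercept,
            training_stats=ErrorStats(
                mad=self.bound, rmsd=float("nan"), msd=float("nan"),
                maxd=float("nan"), n=1182,
            ),
            weights_spec=self.provenance,
        )


PUBLISHED_MODEL = PublishedModel()


def _descriptor_value(d, name: str) -> float:
    if isinstance(d, DescriptorSet):
        if not d.is_defined(name):
            raise ValueError(f"descriptor {name!r} is undefined for this structure")
        return float(getattr(d, name))
    try:
        v = float(d[name])
    except (KeyError, TypeError):
        raise ValueError(f"descriptor {name!r} missing from input") from None
    if np.isnan(v):
        raise ValueError(f"descriptor {name!r} is undefined (NaN)")
    return v


def predict_published(d, model: PublishedModel = PUBLISHED_MODEL):
    """Isomerization-energy estimate from the published coefficients.

    ``d`` is a DescriptorSet or a mapping with sum_dihedral, homa and
    theta_rmsd entries. Returns (estimate, bound) in kcal/mol; negative
    estimates are reported as-is with a warning (they indicate
    extrapolation outside the training manifold).
    """
    sd = _descriptor_value(d, "sum_dihedral")
    h = _descriptor_value(d, "homa")
    tr = _descriptor_value(d, "theta_rmsd")
    estimate = (
        model.sum_dihedral_coef * sd
        + model.homa_coef * h
        + model.theta_rmsd_coef * tr
        + model.intercept
    )
    if estimate < 0:
        warnings.warn(
            f"predicted isomerization energy {estimate:.2f} kcal/mol is negative: "
            "input lies outside the training manifold",
            stacklevel=2,
        )
    return float(estimate), float(model.bound)


def predict(fit: FitResult, d):
    """Apply any FitResult to descriptors.

    ``d`` may be a DescriptorSet, a mapping, a sequence of either, or a
     2-D array whose columns follow fit.descriptor_names. Returns
    (estimates array, bound = training MAD).
    """
    names = fit.descriptor_names
    arr = np.asarray(d) if not isinstance(d, (DescriptorSet, dict)) else None
    if arr is not None and arr.dtype != object and arr.ndim in (1, 2):
        X = np.atleast_2d(arr.astype(float))
    else:
        rows = d if isinstance(d, (list, tuple)) else [d]
        X = np.array(
            [[_descriptor_value(r, name) for name in names] for r in rows]
        )
    est = fit.predict(X)
    return est, float(fit.training_stats.mad)
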