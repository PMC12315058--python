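"""MAD-minimizing linear models of isomerization energy.

Fits are least-absolute-deviation (LAD) regressions solved as linear
programs, so the fitted objective is exactly the (weighted) mean absolute
deviation. Error statistics, semiempirical-energy correction, the optimal
aromatic bond-length scan and per-formula transferability analyses live
here too.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = [
    "ErrorStats",
    "FitResult",
    "CollinearityError",
    "isomerization_energies",
    "error_stats",
    "fit_lad",
    "correct_xtb",
    "planarity_partition",
    "ropt_scan",
    "per_formula_fit",
    "parse_formula",
    "is_in_series",
    "load_isomer_table",
    "add_isomerization_energies",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


@dataclass(frozen=True)
class ErrorStats:
    """Deviation statistics of predictions against references, kcal/mol."""

    mad: float
    rmsd: float
    msd: float
    maxd: float
    n: int

    def as_dict(self) -> dict:
        return {"mad": self.mad, "rmsd": self.rmsd, "msd": self.msd,
                "maxd": self.maxd, "n": self.n}


def error_stats(predicted, reference) -> ErrorStats:
    """MAD / RMSD / MSD / max deviation of predicted - reference."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} vs {reference.shape}"
        )
    if predicted.size == 0:
        raise ValueError("need at least one pair")
    d = predicted - reference
    return ErrorStats(
        mad=float(np.mean(np.abs(d))),
        rmsd=float(np.sqrt(np.mean(d**2))),
        msd=float(np.mean(d)),
        maxd=float(np.max(np.abs(d))),
        n=int(d.size),
    )


def isomerization_energies(energies) -> np.ndarray:
    """Energies relative to the group minimum: E - min(E), kcal/mol."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy group")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    return e - e.min()


@dataclass(frozen=True)
class FitResult:
    """A fitted linear model: names, slopes, intercept and training errors."""

    descriptor_names: tuple
    coefficients: np.ndarray
    intercept: float
    training_stats: ErrorStats
    weights_spec: str = "uniform"

    def __post_init__(self):
        coef = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        if coef.size != len(self.descriptor_names):
            raise ValueError("coefficient count != descriptor count")
        coef = coef.copy()
        coef.setflags(write=False)
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "descriptor_names", tuple(self.descriptor_names))

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.coefficients.size:
            raise ValueError(
                f"expected {self.coefficients.size} descriptor columns, got {X.shape[1]}"
            )
        return self.intercept + X @ self.coefficients

    def to_json(self) -> str:
        return json.dumps(
            {
                "descriptor_names": list(self.descriptor_names),
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "training_stats": self.training_stats.as_dict(),
                "weights_spec": self.weights_spec,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        d = json.loads(text)
        stats = d["training_stats"]
        return cls(
            descriptor_names=tuple(d["descriptor_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            training_stats=ErrorStats(
                mad=stats["mad"], rmsd=stats["rmsd"], msd=stats["msd"],
                maxd=stats["maxd"], n=int(stats["n"]),
            ),
            weights_spec=d.get("weights_spec", "uniform"),
        )


def _check_rank(X1: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X1)
    if rank < X1.shape[1]:
        # pivoted QR exposes which columns are (nearly) dependent
        from scipy.linalg import qr

        _, r, piv = qr(X1, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X1.shape) * np.finfo(float).eps
        bad = sorted(piv[rank:])
        labels = ["intercept"] + list(names)
        raise CollinearityError(
            "design matrix is rank deficient; dependent columns: "
            + ", ".join(labels[j] for j in bad)
        )


def fit_lad(
    X,
    y,
    weights=None,
    names: Optional[Sequence[str]] = None,
) -> FitResult:
    """Least-absolute-deviations fit of y on X with an intercept.

    Minimizes the weighted mean |y - a0 - X a| as a linear program (HiGHS),
    which is deterministic for fixed input. Uniform weights by default.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and np.asarray(y).size != 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if len(y) != n:
        raise ValueError("X and y row counts differ")
    if n <= k:
        raise ValueError(f"need more rows ({n}) than descriptors ({k})")
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if len(names) != k:
        raise ValueError("names length != column count")
    if weights is None:
        w = np.ones(n)
        weights_spec = "uniform"
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative with positive total")
        weights_spec = "per-row"
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")

    X1 = np.column_stack([np.ones(n), X])
    _check_rank(X1, names)

    # variables: [a0, a_1..a_k, u_1..u_n, v_1..v_n]; residual y - X1 b = u - v
    wn = w / w.sum()
    c = np.concatenate([np.zeros(k + 1), wn, wn])
    A_eq = sp.hstack(
        [sp.csr_matrix(X1), sp.identity(n, format="csr"), -sp.identity(n, format="csr")]
    )
    bounds = [(None, None)] * (k + 1) + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LAD linear program failed: {res.message}")
    beta = res.x[: k + 1]
    pred = X1 @ beta
    return FitResult(
        descriptor_names=tuple(names),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        training_stats=error_stats(pred, y),
        weights_spec=weights_spec,
    )


def correct_xtb(e_xtb, e_ref, objective: str = "lad"):
    """Fit a linear correction of semiempirical energies toward the
    reference: corrected = a0 + a1 * e_xtb.

    Both inputs should already be per-formula isomerization energies.
    Returns (FitResult, corrected energies). ``objective`` selects the
    'lad' (default) or 'ls' line of best fit.
    """
    e_xtb = np.asarray(e_xtb, dtype=float)
    e_ref = np.asarray(e_ref, dtype=float)
    if objective == "lad":
        fit = fit_lad(e_xtb.reshape(-1, 1), e_ref, names=["e_xtb"])
    elif objective == "ls":
        A = np.column_stack([np.ones(e_xtb.size), e_xtb])
        beta, *_ = np.linalg.lstsq(A, e_ref, rcond=None)
        pred = A @ beta
        fit = FitResult(
            descriptor_names=("e_xtb",),
            coefficients=beta[1:],
            intercept=float(beta[0]),
            training_stats=error_stats(pred, e_ref),
            weights_spec="uniform (least squares)",
        )
    else:
        raise ValueError("objective must be 'lad' or 'ls'")
    corrected = fit.predict(e_xtb.reshape(-1, 1))
    return fit, corrected


def planarity_partition(table: pd.DataFrame, threshold: float = 1.0,
                        column: str = "delta_z"):
    """Split rows into planar (delta_z <= threshold, boundary inclusive) and
    nonplanar (delta_z > threshold)."""
    if column not in table.columns:
        raise ValueError(f"missing {column!r} column")
    dz = table[column]
    if dz.isna().any():
        raise ValueError(f"{column!r} contains missing values")
    planar = table[dz <= threshold]
    nonplanar = table[dz > threshold]
    return planar, nonplanar


# ---------------------------------------------------------------------------
# optimal-bond-length scan
# ---------------------------------------------------------------------------

def ropt_scan(
    ring_lengths_per_row: Sequence,
    y,
    grid,
    extra_X=None,
    extra_names: Optional[Sequence[str]] = None,
    alpha: float = 257.7,
    weights=None,
):
    """Scan the optimal aromatic bond length of the aromaticity index.

    For each grid value the all-ring index is recomputed from the cached
    per-ring bond lengths (one list of per-ring bond-length lists per row),
    the model refit, and training statistics recorded.

    Returns (DataFrame indexed by r_opt with mad/rmsd/msd/maxd columns,
    best r_opt by training MAD).
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(grid > 5.0):
        raise ValueError("grid must be nonempty within (0, 5] Å")
    y = np.asarray(y, dtype=float)
    rows = []
    for r_opt in grid:
        h = np.array(
            [
                np.mean(
                    [
                        1.0 - alpha / len(L) * np.sum((np.asarray(L) - r_opt) ** 2)
                        for L in per_row
                    ]
                )
                for per_row in ring_lengths_per_row
            ]
        )
        if extra_X is not None:
            X = np.column_stack([h, np.atleast_2d(np.asarray(extra_X, dtype=float))])
            names = ["homa"] + list(extra_names or [f"x{i}" for i in range(X.shape[1] - 1)])
        else:
            X = h.reshape(-1, 1)
            names = ["homa"]
        fit = fit_lad(X, y, weights=weights, names=names)
        s = fit.training_stats
        rows.append((r_opt, s.mad, s.rmsd, s.msd, s.maxd))
    out = pd.DataFrame(rows, columns=["r_opt", "mad", "rmsd", "msd", "maxd"])
    best = float(out.loc[out["mad"].idxmin(), "r_opt"])
    return out, best


# ---------------------------------------------------------------------------
# formula handling and per-formula transferability
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"^C(\d+)H(\d+)$")


def parse_formula(formula: str):
    """Return (n_carbon, n_hydrogen) of a CxHy formula string."""
    m = _FORMULA_RE.match(formula.strip())
    if not m:
        raise ValueError(f"cannot parse hydrocarbon formula {formula!r}")
    return int(m.group(1)), int(m.group(2))


def is_in_series(formula: str) -> bool:
    """Whether a formula belongs to the C(16+4n)H(10+2n) family (n >= 0)."""
    n_c, n_h = parse_formula(formula)
    if n_c < 16 or (n_c - 16) % 4 != 0:
        return False
    return n_h == 10 + (n_c - 16) // 2


def per_formula_fit(
    table: pd.DataFrame,
    descriptor_cols: Sequence[str],
    y_col: str = "e_ref",
    weights_col: Optional[str] = None,
):
    """Fit one model per chemical formula and summarize spread across the
    C(16+4n)H(10+2n) series.

    Groups with too few rows (<= number of descriptors + 1) are skipped with
    a warning. Returns (dict formula -> FitResult, summary dict with the
    in-series labels and max percent deviations of each coefficient and the
    intercept across the in-series formulas).
    """
    missing = [c for c in list(descriptor_cols) + [y_col, "formula"] if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {', '.join(missing)}")
    groups = dict(tuple(table.groupby("formula", sort=True)))
    if len(groups) < 2:
        raise ValueError("need at least 2 formula groups")
    fits = {}
    for formula, grp in groups.items():
        if len(grp) <= len(descriptor_cols) + 1:
            warnings.warn(
                f"formula {formula}: only {len(grp)} rows, skipping fit",
                stacklevel=2,
            )
            continue
        w = grp[weights_col].to_numpy() if weights_col else None
        fits[formula] = fit_lad(
            grp[list(descriptor_cols)].to_numpy(),
            grp[y_col].to_numpy(),
            weights=w,
            names=list(descriptor_cols),
        )

    labels = {f: is_in_series(f) for f in fits}
    series_formulas = sorted(f for f, ok in labels.items() if ok)
    spread = {}
    if len(series_formulas) >= 2:
        coef_mat = np.array([fits[f].coefficients for f in series_formulas])
        intercepts = np.array([fits[f].intercept for f in series_formulas])

        def max_pct_dev(values: np.ndarray) -> float:
            center = values.mean()
            if center == 0:
                return float("inf") if np.any(values != 0) else 0.0
            return float(np.max(np.abs(values - center)) / abs(center) * 100.0)

        for j, name in enumerate(descriptor_cols):
            spread[name] = max_pct_dev(coef_mat[:, j])
        spread["intercept"] = max_pct_dev(intercepts)
    summary = {
        "in_series": labels,
        "series_formulas": series_formulas,
        "max_pct_deviation": spread,
    }
    return fits, summary


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

#: canonical isomer-table columns; anything else is carried through untouched
TABLE_COLUMNS = ("id", "formula", "e_ref", "e_xtb")


def load_isomer_table(path, column_map: Optional[Mapping[str, str]] = None,
                      require: Sequence[str] = ("formula", "e_ref")) -> pd.DataFrame:
    """Read an isomer table CSV, optionally renaming columns.

    ``column_map`` maps source column names to canonical ones (id, formula,
    descriptor names, e_ref, e_xtb), so externally produced descriptor/energy
    exports can be ingested without editing the file.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in require if c not in df.columns]
    if missing:
        raise ValueError(f"isomer table missing columns: {', '.join(missing)}")
    return df


def add_isomerization_energies(
    table: pd.DataFrame,
    energy_cols: Sequence[str] = ("e_ref",),
    group_col: str = "formula",
    prefix: str = "d",
) -> pd.DataFrame:
    """Add per-formula isomerization-energy columns.

    For each energy column ``c`` a column ``<prefix><c>`` is added holding
    the energy minus the minimum of its formula group.
    """
    out = table.copy()
    for c in energy_cols:
        if c not in out.columns:
            raise ValueError(f"missing energy column {c!r}")
        out[prefix + c] = out.groupby(group_col)[c].transform(lambda e: e - e.min())
    return out
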