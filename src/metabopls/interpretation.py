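"""Back-transformed coefficient profiles and metabolite assignment.

After an OPLS-DA fit on scaled data, the discriminatory information is
re-expressed in original intensity units: for every retained bucket the
covariance between the predictive score and the (unscaled, normalized)
bucket intensity gives a coefficient trace that preserves spectral peak
shapes, while the Pearson correlation r between score and bucket colors
that trace by reliability.  With the +1 = control / -1 = COPD class
coding, positive r means the variable is elevated in healthy controls.

Buckets whose |r| clears a significance cutoff — by default the critical
value of the Pearson correlation at P < 0.05 for the modeled sample size —
are matched against a fixed chemical-shift lookup table (the simulator's
metabolite library) to produce a discriminant metabolite table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .chemometrics import OPLSModel, PLSModel
from .cohort import MetaboliteSpec, build_library
from .preprocess import BucketTable

__all__ = [
    "CoefficientProfile",
    "backscaled_profile",
    "critical_r",
    "significant_buckets",
    "assign_ppm",
    "discriminant_table",
    "plot_coefficient_profile",
    "DEFAULT_ASSIGN_TOLERANCE",
]

# Assignment tolerance in ppm, roughly five bucket half-widths of the
# fluid's standard bucketing.
DEFAULT_ASSIGN_TOLERANCE = {"serum": 0.010, "urine": 0.0125}


@dataclass
class CoefficientProfile:
    """Per-bucket covariance (original units) and correlation r with the
    predictive score."""

    bucket_centers: np.ndarray
    covariance: np.ndarray
    r: np.ndarray
    n_samples: int
    fluid: str = "serum"


def _predictive_score(model) -> np.ndarray:
    if isinstance(model, OPLSModel):
        return model.t
    if isinstance(model, PLSModel):
        return model.scores[:, 0]
    raise TypeError(f"unsupported model type {type(model).__name__}")


def backscaled_profile(model, b: BucketTable) -> CoefficientProfile:
    """Covariance/correlation of each bucket with the model's predictive
    score, computed on the original-unit (normalized) bucket matrix."""
    t = _predictive_score(model)
    X = b.matrix
    if X.shape[0] != t.size:
        raise ValueError(
            f"model fitted on {t.size} samples but table has {X.shape[0]}"
        )
    n = t.size
    tc = t - t.mean()
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ tc / (n - 1)
    sx = Xc.std(axis=0, ddof=1)
    st_ = tc.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(sx > 0, cov / (sx * st_), 0.0)
    return CoefficientProfile(
        bucket_centers=b.bucket_centers.copy(),
        covariance=cov,
        r=r,
        n_samples=n,
        fluid=b.fluid,
    )


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical value of the Pearson correlation.

    ``r_crit = t_c / sqrt(t_c² + n - 2)`` with ``t_c`` the Student-t
    quantile at level ``alpha`` on ``n - 2`` degrees of freedom.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t_c = st.t.ppf(1 - alpha / 2.0, n - 2)
    return float(t_c / np.sqrt(t_c**2 + n - 2))


def significant_buckets(profile: CoefficientProfile, cutoff: float) -> np.ndarray:
    """Mask of buckets with |r| strictly above the cutoff."""
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    return np.abs(profile.r) > cutoff


@dataclass(frozen=True)
class PpmMatch:
    metabolite: MetaboliteSpec
    center: float
    multiplicity: str


def assign_ppm(
    ppm_values: Sequence[float] | np.ndarray,
    fluid: str,
    tolerance: float | None = None,
    library: Sequence[MetaboliteSpec] | None = None,
) -> list[list[PpmMatch]]:
    """Match ppm positions against the fluid's chemical-shift lookup table.

    Every library multiplet whose center lies within ``tolerance`` of a
    query ppm is reported; an empty match list marks the position as
    unassigned.
    """
    if library is None:
        library = build_library(fluid)
    if tolerance is None:
        tolerance = DEFAULT_ASSIGN_TOLERANCE[fluid]
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    table = [
        (met, mp.center, mp.multiplicity) for met in library for mp in met.multiplets
    ]
    out: list[list[PpmMatch]] = []
    for ppm in np.asarray(ppm_values, dtype=float):
        out.append(
            [
                PpmMatch(met, center, mult)
                for met, center, mult in table
                if abs(ppm - center) <= tolerance
            ]
        )
    return out


def _shift_list(met: MetaboliteSpec) -> str:
    return ", ".join(f"{mp.center:.2f}({mp.multiplicity})" for mp in met.multiplets)


def discriminant_table(
    profile: CoefficientProfile,
    assignments: list[list[PpmMatch]],
    cutoff: float,
) -> pd.DataFrame:
    """Discriminant metabolite table: one row per metabolite with at least
    one significant assigned bucket.

    ``assignments`` must align with ``profile.bucket_centers`` (one match
    list per bucket, as returned by :func:`assign_ppm`).  The reported r
    is the extreme-|r| value over the metabolite's significant buckets;
    positive r means higher in controls.
    """
    if len(assignments) != profile.bucket_centers.size:
        raise ValueError("assignments do not align with profile buckets")
    sig = significant_buckets(profile, cutoff)
    best: dict[str, tuple[float, MetaboliteSpec]] = {}
    for j, matches in enumerate(assignments):
        if not sig[j]:
            continue
        for m in matches:
            name = m.metabolite.name
            r = float(profile.r[j])
            if name not in best or abs(r) > abs(best[name][0]):
                best[name] = (r, m.metabolite)
    rows = []
    for name in sorted(best):
        r, met = best[name]
        rows.append(
            {
                "metabolite": name,
                "shifts": _shift_list(met),
                "r": r,
                "direction": "higher_in_controls" if r > 0 else "higher_in_copd",
            }
        )
    return pd.DataFrame(rows, columns=["metabolite", "shifts", "r", "direction"])


def plot_coefficient_profile(
    profile: CoefficientProfile, cutoff: float | None = None, path=None
):
    """Render the back-scaled coefficient trace colored by |r|.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    x, y, c = profile.bucket_centers, profile.covariance, np.abs(profile.r)
    pts = np.array([x, y]).T.reshape(-1, 1, 2)
    segments = np.concatenate([pts[:-1], pts[1:]], axis=1)
    lc = LineCollection(segments, cmap="jet", norm=plt.Normalize(0, 1))
    lc.set_array((c[:-1] + c[1:]) / 2)
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.add_collection(lc)
    ax.set_xlim(x.max(), x.min())  # high->low ppm
    pad = 1.1 * max(abs(y.min()), abs(y.max()), 1e-12)
    ax.set_ylim(-pad, pad)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel("covariance with predictive score")
    fig.colorbar(lc, ax=ax, label="|r|")
    if cutoff is not None:
        ax.set_title(f"|r| cutoff = {cutoff:.3f}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
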