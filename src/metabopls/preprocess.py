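"""Spectral preprocessing: referencing, bucketing, normalization, scaling.

The processing chain mirrors standard NMR metabonomics practice: each
spectrum is chemical-shift referenced to a landmark peak (lactate at
1.33 ppm for serum, TSP at 0.00 ppm for urine), integrated over contiguous
fixed-width ppm buckets spanning the analysis region (with solvent /
contaminant windows excluded), normalized to unit total spectral area, and
finally column-scaled (mean centering or unit-variance autoscaling) before
latent-variable modeling.

Two built-in schemes encode the 600 MHz serum and urine conventions:

* ``serum-600``: 9.0–0.5 ppm, 0.002 ppm buckets, excluding 3.69–3.58,
  3.30–3.05, 2.73–2.50 and 1.22–1.16 ppm (residual water, complexes,
  ethanol); referenced to lactate at 1.33 ppm.
* ``urine-600``: 10.0–0.5 ppm, 0.005 ppm buckets, excluding 6.3–5.5
  (residual water) and 5.2–4.4 ppm (urea); referenced to TSP at 0 ppm.

Bucket intervals are half-open ``[low, low + width)`` on a grid anchored at
the region's low edge; every exclusion bound in the built-in schemes falls
exactly on that grid, so no partial buckets arise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cohort import Spectrum

__all__ = [
    "BucketScheme",
    "BucketTable",
    "ScaledMatrix",
    "SCHEMES",
    "get_scheme",
    "bucket_grid",
    "reference_to_peak",
    "bucket_spectrum",
    "normalize_total_area",
    "assemble_matrix",
    "scale_matrix",
]

_GRID_TOL = 1e-9


@dataclass(frozen=True)
class BucketScheme:
    """Bucket geometry: region, width, exclusion windows, reference peak.

    ``region`` and each exclusion window are (high ppm, low ppm) pairs;
    ``reference`` is (target ppm, search half-window ppm).
    """

    region: tuple[float, float]
    width: float
    exclusions: tuple[tuple[float, float], ...] = ()
    reference: tuple[float, float] = (0.0, 0.05)

    def __post_init__(self) -> None:
        high, low = self.region
        if self.width <= 0:
            raise ValueError("bucket width must be > 0")
        if not high > low:
            raise ValueError("region must be (high, low) with high > low")
        self._check_on_grid(high, "region high edge")
        for ehigh, elow in self.exclusions:
            if not ehigh > elow:
                raise ValueError(f"exclusion ({ehigh}, {elow}) must be (high, low)")
            if ehigh > high + _GRID_TOL or elow < low - _GRID_TOL:
                raise ValueError(f"exclusion ({ehigh}, {elow}) outside region {self.region}")
            self._check_on_grid(ehigh, "exclusion bound")
            self._check_on_grid(elow, "exclusion bound")
        spans = sorted((elow, ehigh) for ehigh, elow in self.exclusions)
        for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
            if l2 < h1 - _GRID_TOL:
                raise ValueError("exclusion windows overlap")

    def _check_on_grid(self, bound: float, what: str) -> None:
        low = self.region[1]
        k = (bound - low) / self.width
        if abs(k - round(k)) > 1e-6:
            raise ValueError(
                f"{what} {bound} is not an exact multiple of width {self.width} "
                f"from the region low edge {low}"
            )

    @property
    def n_buckets(self) -> int:
        high, low = self.region
        return int(round((high - low) / self.width))


SCHEMES: dict[str, BucketScheme] = {
    "serum-600": BucketScheme(
        region=(9.0, 0.5),
        width=0.002,
        exclusions=((3.69, 3.58), (3.30, 3.05), (2.73, 2.50), (1.22, 1.16)),
        reference=(1.33, 0.03),
    ),
    "urine-600": BucketScheme(
        region=(10.0, 0.5),
        width=0.005,
        exclusions=((6.3, 5.5), (5.2, 4.4)),
        reference=(0.0, 0.05),
    ),
}

DEFAULT_SCHEME_BY_FLUID = {"serum": "serum-600", "urine": "urine-600"}


def get_scheme(name_or_scheme) -> BucketScheme:
    if isinstance(name_or_scheme, BucketScheme):
        return name_or_scheme
    try:
        return SCHEMES[name_or_scheme]
    except KeyError:
        raise ValueError(
            f"unknown scheme {name_or_scheme!r}; built-ins: {sorted(SCHEMES)}"
        ) from None


def bucket_grid(scheme: BucketScheme) -> tuple[np.ndarray, np.ndarray]:
    """Full bucket-center grid (descending ppm) and the retained mask.

    A bucket is excluded when its interval lies inside any exclusion
    window; because all bounds sit on the grid, buckets are never split.
    """
    high, low = scheme.region
    n = scheme.n_buckets
    edges = low + scheme.width * np.arange(n + 1)  # ascending
    lo, hi = edges[:-1], edges[1:]
    retained = np.ones(n, dtype=bool)
    for ehigh, elow in scheme.exclusions:
        inside = (lo >= elow - _GRID_TOL) & (hi <= ehigh + _GRID_TOL)
        retained &= ~inside
    centers = (lo + hi) / 2.0
    return centers[::-1].copy(), retained[::-1].copy()


@dataclass
class BucketTable:
    """Samples × retained-buckets intensity matrix plus geometry/state."""

    matrix: np.ndarray
    bucket_centers: np.ndarray  # retained buckets, descending ppm
    retained_mask: np.ndarray  # over the full grid, descending ppm
    normalized: bool
    scheme: BucketScheme
    sample_ids: list[str]
    groups: list[str]
    fluid: str = "serum"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[1] != int(self.retained_mask.sum()):
            raise ValueError("matrix columns != retained buckets")
        if self.matrix.shape[1] != self.bucket_centers.size:
            raise ValueError("matrix columns != bucket centers")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise ValueError("sample_ids length != rows")
        if len(self.groups) != self.matrix.shape[0]:
            raise ValueError("groups length != rows")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def subset(self, row_mask: np.ndarray) -> "BucketTable":
        row_mask = np.asarray(row_mask, dtype=bool)
        return BucketTable(
            matrix=self.matrix[row_mask],
            bucket_centers=self.bucket_centers,
            retained_mask=self.retained_mask,
            normalized=self.normalized,
            scheme=self.scheme,
            sample_ids=[s for s, keep in zip(self.sample_ids, row_mask) if keep],
            groups=[g for g, keep in zip(self.groups, row_mask) if keep],
            fluid=self.fluid,
        )


def reference_to_peak(s: Spectrum, scheme: BucketScheme) -> Spectrum:
    """Rigidly shift the ppm axis so the tallest peak near the reference
    target lands exactly on it.

    The apex must exceed 3x the spectrum-wide median intensity, otherwise
    the reference peak is declared missing.
    """
    target, half = scheme.reference
    window = np.abs(s.ppm - target) <= half
    if not window.any():
        raise ValueError(
            f"reference peak not found: no axis points within {target}+/-{half} ppm"
        )
    idx = np.flatnonzero(window)
    apex_local = int(np.argmax(s.intensity[idx]))
    apex = idx[apex_local]
    if not s.intensity[apex] > 3.0 * float(np.median(s.intensity)):
        raise ValueError(
            f"reference peak not found near {target} ppm "
            f"(no peak above 3x median intensity)"
        )
    shift = target - s.ppm[apex]
    return Spectrum(s.ppm + shift, s.intensity.copy(), s.sample_id, s.fluid, s.group)


def bucket_spectrum(s: Spectrum, scheme: BucketScheme) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a spectrum over the scheme's bucket grid.

    Returns the full bucket vector (descending ppm order, excluded buckets
    included) and the retained mask.  Each bucket value is the trapezoidal
    integral of intensity over ``[low, low + width)`` on the native axis,
    with linear interpolation at the interval edges, so the sum over all
    buckets telescopes to the integral over the whole region.
    """
    high, low = scheme.region
    x = s.ppm[::-1]  # ascending
    y = s.intensity[::-1]
    if x[0] > low + _GRID_TOL or x[-1] < high - _GRID_TOL:
        raise ValueError(
            f"spectrum spans [{x[0]:.4f}, {x[-1]:.4f}] ppm; "
            f"narrower than region [{low}, {high}]"
        )
    n = scheme.n_buckets
    edges = low + scheme.width * np.arange(n + 1)
    # cumulative trapezoid of y on the native grid
    seg = 0.5 * (y[1:] + y[:-1]) * np.diff(x)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    # exact cumulative integral at arbitrary edges (linear interp of y)
    i = np.clip(np.searchsorted(x, edges, side="right") - 1, 0, x.size - 2)
    ye = np.interp(edges, x, y)
    F = cum[i] + 0.5 * (y[i] + ye) * (edges - x[i])
    values_asc = np.diff(F)
    centers, retained = bucket_grid(scheme)
    return values_asc[::-1].copy(), retained


def normalize_total_area(v: np.ndarray) -> np.ndarray:
    """Divide a bucket vector by its sum so it integrates to 1."""
    v = np.asarray(v, dtype=float)
    total = float(v.sum())
    if total <= 0:
        raise ValueError(f"cannot normalize: total spectral area {total} <= 0")
    return v / total


def assemble_matrix(samples, scheme, fluid: str | None = None) -> BucketTable:
    """Reference, bucket and normalize every sample; stack rows.

    ``samples`` is either a sequence of :class:`Spectrum` or a manifest
    DataFrame (columns ``sample_id, group, fluid, path``) whose files are
    read on demand.  All samples must share one fluid type; row order
    follows the input order.
    """
    from . import io as _io

    scheme = get_scheme(scheme)
    spectra: list[Spectrum] = []
    if hasattr(samples, "iterrows"):  # manifest DataFrame
        for _, row in samples.iterrows():
            try:
                sp = _io.read_spectrum(row["path"])
            except Exception as exc:
                raise ValueError(f"sample {row['sample_id']}: {exc}") from exc
            sp.sample_id = row["sample_id"]
            sp.group = row["group"]
            sp.fluid = row["fluid"]
            spectra.append(sp)
    else:
        spectra = list(samples)
    if not spectra:
        raise ValueError("empty manifest: no samples to assemble")
    fluids = {sp.fluid for sp in spectra}
    if len(fluids) > 1:
        raise ValueError(f"mixed fluid types in one matrix: {sorted(fluids)}")
    fluid = fluid or spectra[0].fluid

    rows = []
    retained = None
    for sp in spectra:
        try:
            ref = reference_to_peak(sp, scheme)
            full, retained = bucket_spectrum(ref, scheme)
            rows.append(normalize_total_area(full[retained]))
        except ValueError as exc:
            raise ValueError(f"sample {sp.sample_id}: {exc}") from exc
    centers, _ = bucket_grid(scheme)
    return BucketTable(
        matrix=np.vstack(rows),
        bucket_centers=centers[retained],
        retained_mask=retained,
        normalized=True,
        scheme=scheme,
        sample_ids=[sp.sample_id for sp in spectra],
        groups=[sp.group for sp in spectra],
        fluid=fluid,
    )


@dataclass
class ScaledMatrix:
    """Column-scaled data matrix with the statistics needed to back-transform.

    ``method`` is ``mean_center`` or ``unit_variance`` (autoscaling:
    centering followed by division by the column SD).  Columns with zero SD
    under unit-variance scaling are centered and left at zero rather than
    divided by zero; their stored SD is 0 and they are skipped on inverse
    transformation.
    """

    values: np.ndarray
    method: str
    column_means: np.ndarray
    column_sds: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, method: str) -> "ScaledMatrix":
        if method not in ("mean_center", "unit_variance"):
            raise ValueError(f"unknown scaling method {method!r}")
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples to scale")
        means = X.mean(axis=0)
        centered = X - means
        if method == "unit_variance":
            sds = X.std(axis=0, ddof=1)
            safe = np.where(sds > 0, sds, 1.0)
            values = centered / safe
        else:
            sds = np.zeros(X.shape[1])
            values = centered
        return cls(values=values, method=method, column_means=means, column_sds=sds)

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Scale new data with the training statistics."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[-1] != self.column_means.size:
            raise ValueError(
                f"column mismatch: got {X_new.shape[-1]}, expected {self.column_means.size}"
            )
        out = X_new - self.column_means
        if self.method == "unit_variance":
            out = out / np.where(self.column_sds > 0, self.column_sds, 1.0)
        return out

    def inverse(self, V: np.ndarray) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        if self.method == "unit_variance":
            V = V * np.where(self.column_sds > 0, self.column_sds, 1.0)
        return V + self.column_means


def scale_matrix(b: BucketTable | np.ndarray, method: str) -> ScaledMatrix:
    """Scale a bucket table (or raw matrix) by mean centering or autoscaling."""
    X = b.matrix if isinstance(b, BucketTable) else b
    return ScaledMatrix.fit(X, method)
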