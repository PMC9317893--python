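"""Globus pallidus intensity sample, summary statistics and screening.

The GP sample pools voxelwise normalized intensities from both hemispheres.
Five location statistics summarize it: the median, the 60th/70th/80th
percentiles and the Hodges–Lehmann estimator (median of all pairwise Walsh
averages).  The headline screening index is the 60th percentile under
global (mode G) normalization; a subject screens positive when the index
strictly exceeds the cutoff (default 0.994, the published mode-G value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, ExtractionError
from .normalization import MODE_G, MODE_L, NormalizedVolume
from .volume_io import GP_LEFT, GP_RIGHT, LabelMap, require_same_grid

DEFAULT_CUTOFF = 0.994

PERCENTILE_METHOD = "linear"   # interpolation at p*(n-1)/100 on the sorted sample


@dataclass
class GPSample:
    """Pooled bilateral GP intensities in normalized units."""

    values: np.ndarray
    n_left: int
    n_right: int
    mode: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size != self.n_left + self.n_right or self.values.size < 1:
            raise ContractError("sample length must equal n_left + n_right >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("GP sample contains non-finite values")


@dataclass
class IndexSummary:
    """Per-subject GP statistics under one normalization mode."""

    median: float
    p60: float
    p70: float
    p80: float
    hodges_lehmann: float
    mode: str
    n: int

    @property
    def headline_index(self) -> float:
        """The screening index: p60 under mode G."""
        if self.mode != MODE_G:
            raise ContractError("headline index is defined for mode G only")
        return self.p60


@dataclass
class ScreeningResult:
    index: float
    cutoff: float
    positive: bool


def extract_gp_sample(volume: NormalizedVolume, seg: LabelMap) -> GPSample:
    """Pool GP voxel intensities from both hemispheres.

    Raises :class:`ExtractionError` when the segmentation contains no GP
    voxels (the subject is flagged unanalyzable rather than scored).
    """
    require_same_grid(volume, seg, "normalized volume and segmentation")
    left = seg.mask(GP_LEFT)
    right = seg.mask(GP_RIGHT)
    nl, nr = int(left.sum()), int(right.sum())
    if nl + nr == 0:
        raise ExtractionError("segmentation contains zero GP voxels")
    values = np.concatenate([volume.data[left], volume.data[right]])
    return GPSample(values, nl, nr, volume.mode)


def histogram(sample: GPSample, n_bins: int = 64
              ) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram over [min, max]; counts sum to the sample size."""
    if n_bins < 1:
        raise ContractError("n_bins must be >= 1")
    lo, hi = float(sample.values.min()), float(sample.values.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(sample.values, bins=n_bins, range=(lo, hi))
    return edges, counts


def percentile(values: np.ndarray, p: float) -> float:
    """Linear-interpolation percentile at rank position p*(n-1)/100."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ContractError("empty sample")
    if not (0.0 <= p <= 100.0):
        raise ContractError(f"percentile must be in [0, 100], got {p}")
    return float(np.percentile(values, p, method=PERCENTILE_METHOD))


def hodges_lehmann(values: np.ndarray) -> float:
    """Median of all Walsh averages (x_i + x_j)/2 over i <= j (i = j included)."""
    values = np.asarray(values, dtype=np.float64).ravel()
    n = values.size
    if n == 0:
        raise ContractError("empty sample")
    walsh = (values[:, None] + values[None, :]) / 2.0
    iu = np.triu_indices(n)
    return float(np.median(walsh[iu]))


def summarize(sample: GPSample) -> IndexSummary:
    """All five statistics of the pooled sample."""
    v = sample.values
    return IndexSummary(
        median=percentile(v, 50.0),
        p60=percentile(v, 60.0),
        p70=percentile(v, 70.0),
        p80=percentile(v, 80.0),
        hodges_lehmann=hodges_lehmann(v),
        mode=sample.mode,
        n=int(v.size),
    )


def classify(summary: IndexSummary, cutoff: float | None = None
             ) -> ScreeningResult:
    """Screen a subject: positive iff index strictly exceeds the cutoff.

    The published cutoff is mode-G specific; a mode-L summary requires an
    explicit cutoff override.
    """
    if cutoff is None:
        if summary.mode != MODE_G:
            raise ContractError(
                "the default cutoff applies to mode G; pass an explicit "
                "cutoff for mode L summaries")
        cutoff = DEFAULT_CUTOFF
    if summary.mode == MODE_G:
        index = summary.headline_index
    else:
        index = summary.p60
    return ScreeningResult(index=float(index), cutoff=float(cutoff),
                           positive=bool(index > cutoff))


def summary_statistics(summary: IndexSummary) -> dict[str, float]:
    """The five statistics keyed by their canonical row names."""
    return {
        "median": summary.median,
        "p60": summary.p60,
        "p70": summary.p70,
        "p80": summary.p80,
        "hodges_lehmann": summary.hodges_lehmann,
    }
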