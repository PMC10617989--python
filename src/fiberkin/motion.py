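"""Displacement statistics and PCA motion decomposition.

Dorsoventral displacement of the tracked fiber is measured per 2-um bin
along the rostrocaudal axis as the absolute deviation of the bin-mean
curve from its temporal mean, reported in nanometres.  Group summaries
compare regions (rostral/middle/caudal, defined by somites 1-10/11-20/
21-30) or conditions (live vs fixed) with an unpaired t-test (two
groups) or Tukey's HSD (more), at both the pooled bin-frame granularity
and per-fish medians.

The spatial PCA treats each frame as one observation over all pixels
(mean-centered in time, no whitening); component images, temporal
scores and percent-of-variance fractions are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ImageSequence
from .tracking import FiberTrace

__all__ = ["DisplacementTable", "MotionComponents", "RegionSummary",
           "bin_and_displace", "summarize_regions", "pca_motion"]


@dataclass
class DisplacementTable:
    """Per-bin dorsoventral displacement from the temporal mean.

    ``displacement_nm`` has shape (n_frames, n_bins); bins with no valid
    column in a frame are NaN (marked missing, never interpolated).
    """

    bin_centers_um: np.ndarray
    displacement_nm: np.ndarray
    y_um: np.ndarray                 # bin-mean dorsoventral position
    region: str | None = None
    fish: str | None = None

    def to_dataframe(self) -> pd.DataFrame:
        f, b = np.meshgrid(np.arange(self.displacement_nm.shape[0]),
                           self.bin_centers_um, indexing="ij")
        out = pd.DataFrame({
            "frame": f.ravel(), "bin_center_um": b.ravel(),
            "displacement_nm": self.displacement_nm.ravel(),
        })
        if self.region is not None:
            out["region"] = self.region
        if self.fish is not None:
            out["fish"] = self.fish
        return out

    def median_profile(self) -> np.ndarray:
        """Per-bin median displacement over frames, nm."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(self.displacement_nm, axis=0)


def bin_and_displace(trace: FiberTrace, bin_um: float = 2.0,
                     region: str | None = None,
                     fish: str | None = None) -> DisplacementTable:
    """Discretize the tracked curve in rostrocaudal bins and measure
    dorsoventral displacement from the temporal mean, in nm.

    The bin position is the mean of the curve over the bin's valid
    columns; displacement(bin, t) = |y(bin, t) - mean_t y(bin)|.
    Operating on the full trace is equivalent to the crop-and-concatenate
    bookkeeping sometimes used on real recordings, since per-bin temporal
    means are unaffected by how the field of view is pieced apart.
    """
    if trace.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if bin_um <= 0:
        raise ValueError("bin_um must be positive")
    x_um = trace.x_um
    y_um = trace.y_um
    bins = np.floor(x_um / bin_um).astype(int)
    nbin = bins.max() + 1

    y_bin = np.full((trace.n_frames, nbin), np.nan)
    for b in range(nbin):
        cols = bins == b
        sel = trace.valid[:, cols]                       # (T, n_cols_in_bin)
        vals = np.where(sel, y_um[:, cols], np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            y_bin[:, b] = np.nanmean(vals, axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_t = np.nanmean(y_bin, axis=0)
    disp_nm = np.abs(y_bin - mean_t[None, :]) * 1000.0
    centers = (np.arange(nbin) + 0.5) * bin_um
    return DisplacementTable(bin_centers_um=centers, displacement_nm=disp_nm,
                             y_um=y_bin, region=region, fish=fish)


@dataclass
class RegionSummary:
    """Group comparison of displacement observations."""

    per_group: pd.DataFrame          # median, sd, n per group
    per_fish: pd.DataFrame | None    # per-fish medians (if fish ids given)
    ttest: dict | None               # two-group unpaired two-tailed t-test
    tukey: object | None             # statsmodels TukeyHSDResults
    observation_unit: str = "bin-frame"

    def summary(self) -> str:
        lines = ["Displacement summary (nm, median +/- SD per group)"]
        for _, r in self.per_group.iterrows():
            lines.append(f"  {r['group']}: {r['median']:.0f} +/- {r['sd']:.0f}"
                         f" (n={int(r['n'])})")
        if self.ttest is not None:
            lines.append(f"  unpaired two-tailed t-test: t={self.ttest['t']:.3g},"
                         f" p={self.ttest['p']:.3g}")
        if self.tukey is not None:
            lines.append(str(self.tukey))
        return "\n".join(lines)


def summarize_regions(observations: pd.DataFrame,
                      value: str = "displacement_nm",
                      group: str = "group",
                      fish: str | None = None) -> RegionSummary:
    """Summarize and compare displacement distributions across groups.

    ``observations`` is a long table with one displacement value per row
    (pooled bin-frame values), a group label column, and optionally a
    fish id column for per-fish medians.  Two groups are compared with
    an unpaired two-tailed t-test, three or more with Tukey's HSD on the
    pooled observations; per-fish medians are reported separately since
    the natural observation unit is ambiguous on real data.
    """
    df = observations.dropna(subset=[value])
    sizes = df.groupby(group)[value].size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"groups excluded with <2 observations: {small}")
        df = df[~df[group].isin(small)]
    groups = df[group].unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >=2 observations")

    per_group = (df.groupby(group)[value]
                 .agg(median="median", sd="std", n="size")
                 .reset_index().rename(columns={group: "group"}))

    per_fish = None
    if fish is not None:
        per_fish = (df.groupby([group, fish])[value].median()
                    .reset_index().rename(columns={group: "group",
                                                   value: "median"}))

    ttest = None
    tukey = None
    if len(groups) == 2:
        a = df.loc[df[group] == groups[0], value]
        b = df.loc[df[group] == groups[1], value]
        t, p = stats.ttest_ind(a, b)
        ttest = {"t": float(t), "p": float(p),
                 "groups": (str(groups[0]), str(groups[1]))}
    else:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        tukey = pairwise_tukeyhsd(df[value].to_numpy(),
                                  df[group].to_numpy())
    return RegionSummary(per_group=per_group, per_fish=per_fish,
                         ttest=ttest, tukey=tukey)


@dataclass
class MotionComponents:
    """Spatial principal components of a movie.

    ``components`` are orthonormal images (n_components, H, W), defined
    up to sign; ``variance_fraction`` in percent of the total temporal
    variance, non-increasing; ``scores`` are per-frame projections.
    """

    components: np.ndarray
    variance_fraction: np.ndarray
    scores: np.ndarray
    mean_image: np.ndarray = field(repr=False, default=None)

    def plot(self, k: int = 0, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.components[k], cmap="gray")
        ax.set_title(f"component {k + 1}: "
                     f"{self.variance_fraction[k]:.1f}% of variance")
        return im


def pca_motion(seq: ImageSequence, n_components: int = 5) -> MotionComponents:
    """PCA of a movie with frames as observations and pixels as variables.

    Frames are mean-centered over time; an exact SVD of the centered
    frame matrix gives orthonormal component images, temporal scores and
    percent-of-total-temporal-variance fractions.
    """
    frames = np.asarray(seq.data, dtype=float)
    n, h, w = frames.shape
    if n < 2:
        raise ValueError("need at least 2 frames")
    X = frames.reshape(n, -1)
    Xc = X - X.mean(axis=0)
    total = np.sum(Xc**2)
    if total <= 0:
        raise ValueError("constant movie: zero temporal variance, "
                         "variance fractions undefined")
    k = min(n_components, n - 1, X.shape[1])
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    frac = 100.0 * (s**2) / np.sum(s**2)
    return MotionComponents(
        components=Vt[:k].reshape(k, h, w),
        variance_fraction=frac[:k],
        scores=(U[:, :k] * s[:k]),
        mean_image=X.mean(axis=0).reshape(h, w),
    )
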