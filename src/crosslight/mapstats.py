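"""Nonparametric inference on accuracy maps.

Group-level: a two-sample pseudo-t with variance smoothing (mask-aware
Gaussian, default sigma = 6 mm), threshold-free cluster enhancement (TFCE)
and max-statistic permutation testing controlling the family-wise error rate.
Subject-level: the same machinery applied to per-partition accuracies of an
observed map versus its empirical (label-permuted) null map.

Testing is one-sided (accuracy above the null); negative statistic values
contribute nothing to TFCE.  Permutation p-values use the add-one estimator
p = (1 + #{perm max >= observed}) / (n_perm + 1), so p in [1/(n_perm+1), 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["GroupMaps", "TfceParams", "smooth_volume",
           "pseudo_t_two_sample", "tfce", "permutation_fwe",
           "subject_level_test", "max_stat_randomization_p"]


@dataclass
class GroupMaps:
    """Subjects x centers matrix of mean accuracies on a shared mask."""

    values: np.ndarray          # (n_subjects, n_centers)
    mask: object                # BrainMask; centers = mask.coords order
    tag: str = "observed"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_subjects, n_centers)")
        if self.values.shape[1] != self.mask.n_voxels:
            raise ValueError("center count does not match mask")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class TfceParams:
    """TFCE settings: extent exponent E, height exponent H, integration step
    dh ('auto' = max/100) and cluster connectivity (6, 18 or 26)."""

    E: float = 0.5
    H: float = 2.0
    dh: float | str = "auto"
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be nonnegative")
        if self.dh != "auto" and not self.dh > 0:
            raise ValueError("dh must be positive or 'auto'")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


def _to_volume(flat: np.ndarray, mask) -> np.ndarray:
    vol = np.zeros(mask.shape)
    vol[mask.inside] = flat
    return vol


def smooth_volume(values: np.ndarray, mask, sigma_mm: float) -> np.ndarray:
    """Mask-aware Gaussian smoothing of per-voxel values (flat, mask order).

    The kernel is renormalized over the in-mask support, so a constant map is
    preserved exactly; sigma_mm = 0 is the identity.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be nonnegative")
    values = np.asarray(values, dtype=float)
    if sigma_mm == 0:
        return values.copy()
    sigma_vox = sigma_mm / mask.voxel_size_mm
    vol = _to_volume(values, mask)
    num = ndimage.gaussian_filter(vol, sigma_vox)
    den = ndimage.gaussian_filter(mask.inside.astype(float), sigma_vox)
    out = np.zeros_like(vol)
    inside = mask.inside & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out[mask.inside]


def pseudo_t_two_sample(a: GroupMaps, b: GroupMaps,
                        sigma_mm: float = 6.0) -> np.ndarray:
    """Two-sample t with variance smoothing:
    t = (mean_a - mean_b) / sqrt(v_smooth * (1/n_a + 1/n_b)), with v_smooth
    the mask-smoothed pooled variance.  Degenerate voxels (zero smoothed
    variance and zero difference) yield statistic 0."""
    if a.values.shape[1] != b.values.shape[1]:
        raise ValueError("groups must share centers")
    na, nb = a.n_subjects, b.n_subjects
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    return _pseudo_t(a.values, b.values, a.mask, sigma_mm)


def _pseudo_t(va: np.ndarray, vb: np.ndarray, mask,
              sigma_mm: float) -> np.ndarray:
    na, nb = va.shape[0], vb.shape[0]
    diff = va.mean(axis=0) - vb.mean(axis=0)
    pooled = ((na - 1) * va.var(axis=0, ddof=1)
              + (nb - 1) * vb.var(axis=0, ddof=1)) / (na + nb - 2)
    v_s = smooth_volume(pooled, mask, sigma_mm)
    se = np.sqrt(np.maximum(v_s, 0.0) * (1.0 / na + 1.0 / nb))
    t = np.zeros_like(diff)
    ok = se > 0
    t[ok] = diff[ok] / se[ok]
    # zero smoothed variance with a nonzero difference: sign at infinity,
    # capped to a large finite value to keep downstream TFCE finite
    t[~ok & (diff != 0)] = np.sign(diff[~ok & (diff != 0)]) * 1e12
    return t


def tfce(stat: np.ndarray, mask, params: TfceParams | None = None
         ) -> np.ndarray:
    """One-sided threshold-free cluster enhancement of a flat statistic map.

    TFCE(v) = sum over thresholds h = dh, 2dh, ... <= stat(v) of
    extent(cluster of v at h)^E * h^H * dh, clusters by the chosen
    connectivity; negative values contribute 0.
    """
    params = params or TfceParams()
    stat = np.asarray(stat, dtype=float)
    pos = np.clip(stat, 0.0, None)
    hmax = float(pos.max(initial=0.0))
    out = np.zeros_like(pos)
    if hmax <= 0:
        return out
    dh = hmax / 100.0 if params.dh == "auto" else float(params.dh)
    vol = _to_volume(pos, mask)
    structure = params.structure()
    n_steps = int(np.floor(hmax / dh + 1e-9))
    acc = np.zeros(mask.shape)
    for i in range(1, n_steps + 1):
        h = i * dh
        above = vol >= h
        if not above.any():
            break
        lab, n_lab = ndimage.label(above, structure=structure)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        acc += np.where(above, sizes[lab] ** params.E * h ** params.H * dh,
                        0.0)
    return acc[mask.inside]


def _pseudo_t_paired(diffs: np.ndarray, mask, sigma_mm: float) -> np.ndarray:
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    v_s = smooth_volume(diffs.var(axis=0, ddof=1), mask, sigma_mm)
    se = np.sqrt(np.maximum(v_s, 0.0) / n)
    t = np.zeros_like(mean)
    ok = se > 0
    t[ok] = mean[ok] / se[ok]
    t[~ok & (mean != 0)] = np.sign(mean[~ok & (mean != 0)]) * 1e12
    return t


def permutation_fwe(a: GroupMaps, b: GroupMaps, n_perm: int = 10000,
                    sigma_mm: float = 6.0,
                    tfce_params: TfceParams | None = None,
                    seed: int = 0, paired: bool = False) -> np.ndarray:
    """Max-statistic FWE permutation test that group a exceeds group b.

    Group membership is relabeled uniformly at random n_perm times; for each
    relabeling the pseudo-t -> TFCE -> spatial maximum is recorded, and
    p_v = (1 + #{perm max >= observed TFCE_v}) / (n_perm + 1).

    With ``paired=True`` (equal group sizes, row i of a paired with row i of
    b) the test becomes a one-sample sign-flip test on the per-pair
    difference maps, exchanging a_i and b_i at random instead of freely
    relabeling rows.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if a.n_subjects < 2 or b.n_subjects < 2:
        raise ValueError("groups of size < 2 are not permutable")
    tfce_params = tfce_params or TfceParams()
    mask = a.mask
    rng = np.random.default_rng(seed)
    max_stats = np.empty(n_perm)
    if paired:
        if a.n_subjects != b.n_subjects:
            raise ValueError("paired test needs equal group sizes")
        diffs = a.values - b.values
        obs = tfce(_pseudo_t_paired(diffs, mask, sigma_mm), mask,
                   tfce_params)
        for j in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=diffs.shape[0])
            t = _pseudo_t_paired(diffs * signs[:, None], mask, sigma_mm)
            max_stats[j] = tfce(t, mask, tfce_params).max(initial=0.0)
    else:
        obs = tfce(_pseudo_t(a.values, b.values, mask, sigma_mm), mask,
                   tfce_params)
        combined = np.vstack([a.values, b.values])
        na = a.n_subjects
        for j in range(n_perm):
            perm = rng.permutation(combined.shape[0])
            va, vb = combined[perm[:na]], combined[perm[na:]]
            t = _pseudo_t(va, vb, mask, sigma_mm)
            max_stats[j] = tfce(t, mask, tfce_params).max(initial=0.0)
    exceed = (max_stats[None, :] >= obs[:, None]).sum(axis=1)
    return (1.0 + exceed) / (n_perm + 1.0)


def subject_level_test(observed: np.ndarray, null: np.ndarray, mask,
                       n_perm: int = 1000, seed: int = 0,
                       sigma_mm: float = 0.0,
                       tfce_params: TfceParams | None = None) -> np.ndarray:
    """Per-subject FWE test: observed vs null per-partition accuracies.

    ``observed`` and ``null`` are (n_centers, n_partitions) stacks from a
    searchlight run and its label-permuted null (equal partition counts).
    Partitions play the role of exchangeable observations in a two-sample
    permutation test per voxel, with max-statistic FWE across voxels.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.shape != null.shape:
        raise ValueError("observed and null must have equal partition counts")
    if observed.shape[1] < 2:
        raise ValueError("need at least 2 partitions")
    a = GroupMaps(values=observed.T, mask=mask, tag="observed")
    b = GroupMaps(values=null.T, mask=mask, tag="null")
    return permutation_fwe(a, b, n_perm=n_perm, sigma_mm=sigma_mm,
                           tfce_params=tfce_params, seed=seed)


def max_stat_randomization_p(observed: np.ndarray,
                             null_columns: np.ndarray) -> np.ndarray:
    """Max-statistic FWE p-values from labeling-level randomization.

    ``observed`` is the per-voxel statistic under the true labeling (e.g. a
    mean accuracy map) and ``null_columns`` is (n_voxels, L) holding the same
    statistic under L random relabelings, each computed by the identical
    pipeline.  p_v = (1 + #{l : max_w null[w, l] >= observed_v}) / (L + 1);
    the smallest attainable p is 1/(L+1).
    """
    observed = np.asarray(observed, dtype=float)
    null_columns = np.asarray(null_columns, dtype=float)
    if null_columns.ndim != 2 or null_columns.shape[0] != len(observed):
        raise ValueError("null_columns must be (n_voxels, n_labelings)")
    maxima = null_columns.max(axis=0)
    exceed = (maxima[None, :] >= observed[:, None]).sum(axis=1)
    return (1.0 + exceed) / (null_columns.shape[1] + 1.0)
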