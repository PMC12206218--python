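"""Trial-constrained train/test partitioning for source and target domains.

Samples within a trial are temporally correlated, so a trial must never
straddle a train/test divide.  The source domain is split at the trial level
with approximate class stratification (default 4:1 train:test).  The target
domain contributes exactly ``N_t`` training samples drawn with approximate
class stratification; every remaining sample of a touched trial is discarded
and the untouched trials form the test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplitSpec",
    "source_split",
    "target_split",
    "ungrouped_split",
    "make_partitions",
]


@dataclass
class SplitSpec:
    """One reproducible partition of source and target data."""

    source_train: np.ndarray
    source_test: np.ndarray
    target_train: np.ndarray
    target_test: np.ndarray
    N_t: int
    seed: int
    target_discarded: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self) -> None:
        for name in ("source_train", "source_test", "target_train",
                     "target_test", "target_discarded"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        if len(self.target_train) != self.N_t:
            raise ValueError("target_train must hold exactly N_t samples")
        if np.intersect1d(self.source_train, self.source_test).size:
            raise ValueError("source train/test overlap")
        tgt = [self.target_train, self.target_test, self.target_discarded]
        for i in range(3):
            for j in range(i + 1, 3):
                if np.intersect1d(tgt[i], tgt[j]).size:
                    raise ValueError("target index sets overlap")

    def validate_trials(self, source, target) -> None:
        """Assert trial atomicity against the datasets this spec indexes."""
        s_tr = set(source.trial_id[self.source_train])
        s_te = set(source.trial_id[self.source_test])
        if s_tr & s_te:
            raise ValueError("a source trial straddles train/test")
        t_tr = set(target.trial_id[self.target_train])
        t_te = set(target.trial_id[self.target_test])
        if t_tr & t_te:
            raise ValueError("a target trial straddles train/test")

    def to_json(self) -> str:
        return json.dumps({
            "source_train": self.source_train.tolist(),
            "source_test": self.source_test.tolist(),
            "target_train": self.target_train.tolist(),
            "target_test": self.target_test.tolist(),
            "target_discarded": self.target_discarded.tolist(),
            "N_t": int(self.N_t),
            "seed": int(self.seed),
        })

    @classmethod
    def from_json(cls, s: str) -> "SplitSpec":
        d = json.loads(s)
        return cls(
            source_train=d["source_train"], source_test=d["source_test"],
            target_train=d["target_train"], target_test=d["target_test"],
            N_t=d["N_t"], seed=d["seed"],
            target_discarded=np.asarray(d["target_discarded"], int),
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def source_split(data, test_fraction: float = 0.2, seed: int = 0):
    """Whole-trial, per-class stratified split of the source domain.

    Per class, round(test_fraction * n_class_trials) trials (at least 1) go to
    the test side; rounding is half-up.  Returns (train_idx, test_idx).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_trials = []
    for cls in (0, 1):
        trials = np.unique(data.trial_id[data.y == cls])
        if len(trials) < 2:
            raise ValueError(f"class {cls} has fewer than 2 trials")
        n_test = max(1, _round_half_up(test_fraction * len(trials)))
        test_trials.append(rng.permutation(trials)[:n_test])
    test_trials = np.concatenate(test_trials)
    is_test = np.isin(data.trial_id, test_trials)
    return np.flatnonzero(~is_test), np.flatnonzero(is_test)


def ungrouped_split(data, test_fraction: float = 0.2, seed: int = 0):
    """Sample-level random split that IGNORES the trial constraint.

    Diagnostic only: demonstrates the optimistic bias (trial leakage) that the
    grouped :func:`source_split` prevents.  Never use for reported results.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = data.n_samples
    perm = rng.permutation(n)
    n_test = max(1, _round_half_up(test_fraction * n))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def target_split(data, N_t: int, seed: int = 0):
    """Draw N_t stratified target training samples; discard trial leftovers.

    ceil(N_t/2) samples come from one class and floor(N_t/2) from the other;
    for odd N_t the class receiving the larger half is chosen by a
    seed-dependent coin flip.  Within each class the quota is filled trial by
    trial (trial order and within-trial sample order both randomized), so the
    selection touches as few trials as the quota allows and a usable test set
    of whole untouched trials remains even when N_t is a large fraction of
    the target data.  Remaining samples of any touched trial are discarded
    (neither train nor test); the test set is every sample of the untouched
    trials.  Returns (train_idx, test_idx, discarded_idx).
    """
    rng = np.random.default_rng(seed)
    if N_t == 0:
        return (np.array([], int), np.arange(data.n_samples),
                np.array([], int))
    n_hi, n_lo = int(np.ceil(N_t / 2)), int(np.floor(N_t / 2))
    if rng.integers(2) == 0:
        n_per_class = {0: n_hi, 1: n_lo}
    else:
        n_per_class = {0: n_lo, 1: n_hi}
    train = []
    for cls in (0, 1):
        quota = n_per_class[cls]
        trials = rng.permutation(np.unique(data.trial_id[data.y == cls]))
        taken = 0
        for i, t in enumerate(trials):
            if quota == 0:
                break
            idx = np.flatnonzero(data.trial_id == t)
            take = min(quota, len(idx))
            train.append(rng.permutation(idx)[:take])
            quota -= take
            taken = i + 1
        if quota > 0:
            raise ValueError(f"N_t exhausts class {cls}")
        if taken >= len(trials):
            raise ValueError(
                f"N_t={N_t} touches every trial of class {cls}; "
                "no full trial left for testing")
    train = np.sort(np.concatenate(train))
    touched = np.unique(data.trial_id[train])
    in_touched = np.isin(data.trial_id, touched)
    test = np.flatnonzero(~in_touched)
    discarded = np.setdiff1d(np.flatnonzero(in_touched), train)
    return train, test, discarded


def make_partitions(source, target, n_partitions: int = 100,
                    N_t: int = 100, base_seed: int = 0,
                    test_fraction: float = 0.2) -> list[SplitSpec]:
    """Build n_partitions reproducible SplitSpecs; partition p (1-based)
    uses seed base_seed + p for both domain splits."""
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    specs = []
    for p in range(1, n_partitions + 1):
        seed = base_seed + p
        s_tr, s_te = source_split(source, test_fraction, seed)
        t_tr, t_te, t_disc = target_split(target, N_t, seed)
        spec = SplitSpec(source_train=s_tr, source_test=s_te,
                         target_train=t_tr, target_test=t_te,
                         N_t=N_t, seed=seed, target_discarded=t_disc)
        spec.validate_trials(source, target)
        specs.append(spec)
    return specs
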