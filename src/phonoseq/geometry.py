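"""Displacement-vector representational geometry.

Marginal (wildcard) condition means, factor displacement vectors, the
compositional leave-one-condition-out predictor across sequence lengths,
best-fit 2-D plane variance, and cross-positional correlation matrices.

All operations act on generic point sets (trials x coordinates) so they run
equally in full feature space or in a decoder's discriminant-component
space — the space is the caller's choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DesignError, EmptySelectionError, ShapeError
from .preprocess import EpochWindow, extract_windows
from .session import SessionData
from .task import ConditionLabel


# ---------------------------------------------------------------------------
# marginal means
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Which label attributes define a marginal group.

    ``slots`` lists 1-based consonant positions whose identity is kept;
    every unlisted slot is a wildcard (marginalized over).  The all-wildcard
    spec groups everything into the grand mean.
    """

    slots: tuple[int, ...] = ()
    by_length: bool = False
    by_boundary: bool = False

    def __post_init__(self):
        object.__setattr__(self, "slots", tuple(sorted(self.slots)))

    def key(self, label: ConditionLabel):
        if label.is_rest or (self.slots and
                             label.length_class < max(self.slots)):
            return None
        parts: list = []
        if self.by_length:
            parts.append(("length", label.length_class))
        if self.by_boundary:
            parts.append(("words", label.n_words))
        for p in self.slots:
            parts.append((p, label.consonant_at(p)))
        return tuple(parts)

    def nests_in(self, base: "GroupSpec") -> bool:
        return (set(base.slots) <= set(self.slots)
                and (not base.by_length or self.by_length)
                and (not base.by_boundary or self.by_boundary))

    @staticmethod
    def restrict_key(key, base: "GroupSpec"):
        parts = []
        for tag, val in key:
            if tag == "length" and base.by_length:
                parts.append((tag, val))
            elif tag == "words" and base.by_boundary:
                parts.append((tag, val))
            elif isinstance(tag, int) and tag in base.slots:
                parts.append((tag, val))
        return tuple(parts)

    def pattern(self, key, n_slots: int) -> str:
        """Wildcard string, e.g. ``*ah*ahSH`` for slot-3 grouping."""
        tokens = {tag: val for tag, val in key if isinstance(tag, int)}
        out = ""
        for p in range(1, n_slots + 1):
            out += tokens.get(p, "*") + "ah"
        return out[:-2] if n_slots else "*"


@dataclass
class MarginalMeanSet:
    spec: GroupSpec
    means: dict
    counts: dict
    empty_groups: list = field(default_factory=list)

    def mean(self, key) -> np.ndarray:
        return self.means[key]


def marginal_means(points: np.ndarray, labels, spec: GroupSpec
                   ) -> MarginalMeanSet:
    """Group means of trial coordinates under a wildcard grouping.

    Trials whose labels do not cover the grouped slots are skipped; groups
    that end up empty are excluded and reported with zero count.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] != len(labels):
        raise ShapeError("points must be trials x coords matching labels")
    sums: dict = {}
    counts: dict = {}
    for x, lab in zip(points, labels):
        key = spec.key(lab)
        if key is None:
            continue
        if key not in sums:
            sums[key] = np.zeros(points.shape[1])
            counts[key] = 0
        sums[key] += x
        counts[key] += 1
    if not sums:
        raise EmptySelectionError("grouping matched no trials")
    means = {k: sums[k] / counts[k] for k in sums}
    return MarginalMeanSet(spec=spec, means=means, counts=counts)


@dataclass
class DisplacementSet:
    base: MarginalMeanSet
    refined: MarginalMeanSet
    vectors: dict                # refined key -> refined mean - base mean

    def base_key(self, key):
        return GroupSpec.restrict_key(key, self.base.spec)


def displacement_vectors(base: MarginalMeanSet, refined: MarginalMeanSet
                         ) -> DisplacementSet:
    """Refined-group means minus their enclosing base-group means.

    In a balanced design the count-weighted displacements within each base
    group sum to the zero vector.
    """
    if not refined.spec.nests_in(base.spec):
        raise DesignError("refined grouping does not nest inside base")
    vectors = {}
    for key, mean in refined.means.items():
        bkey = GroupSpec.restrict_key(key, base.spec)
        if bkey not in base.means:
            raise DesignError(f"no base group for refined group {key}")
        vectors[key] = mean - base.means[bkey]
    return DisplacementSet(base=base, refined=refined, vectors=vectors)


# ---------------------------------------------------------------------------
# compositional leave-one-condition-out prediction
# ---------------------------------------------------------------------------

@dataclass
class CompositionalReport:
    r2_condition: float
    r2_single_trial: float
    ci_condition: tuple[float, float] | None
    ci_single_trial: tuple[float, float] | None
    p_condition: float | None
    p_single_trial: float | None
    n_perm: int
    class_means: dict
    predictions: dict


def _class_structures(points, labels):
    keys = [(lab.length_class, lab.consonant_at(1)) for lab in labels]
    classes = sorted(set(keys))
    lengths = sorted({k[0] for k in classes})
    by_class = {c: np.array([i for i, k in enumerate(keys) if k == c])
                for c in classes}
    by_length = {L: np.array([i for i, k in enumerate(keys) if k[0] == L])
                 for L in lengths}
    return keys, classes, lengths, by_class, by_length


def _predict_classes(points, labels, donor_lengths: str = "others"):
    """Leave-one-class-out compositional predictions in coordinate space."""
    keys, classes, lengths, by_class, by_length = _class_structures(
        points, labels
    )
    if len(lengths) < 2 and donor_lengths == "others":
        raise DesignError("need >= 2 sequence-length classes")
    cmeans = {c: points[by_class[c]].mean(axis=0) for c in classes}
    lmeans = {L: points[by_length[L]].mean(axis=0) for L in lengths}
    disp = {c: cmeans[c] - lmeans[c[0]] for c in classes}

    def mean_norm(L, exclude_cons):
        norms = [np.linalg.norm(disp[c]) for c in classes
                 if c[0] == L and c[1] != exclude_cons]
        return float(np.mean(norms)) if norms else 0.0

    preds = {}
    for L, cons in classes:
        donors = [Lp for Lp in lengths
                  if (Lp, cons) in disp
                  and (Lp != L if donor_lengths == "others" else Lp == L)]
        if not donors:
            preds[(L, cons)] = lmeans[L]
            continue
        target_norm = mean_norm(L, cons)
        terms = []
        for Lp in donors:
            donor_norm = mean_norm(Lp, cons)
            scale = target_norm / donor_norm if donor_norm > 0 else 1.0
            terms.append(scale * disp[(Lp, cons)])
        preds[(L, cons)] = lmeans[L] + np.mean(terms, axis=0)
    return keys, cmeans, preds


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    """Multivariate R² over all coordinates (component-variance weighted)."""
    obs, pred = np.asarray(obs, float), np.asarray(pred, float)
    sse = np.sum((obs - pred) ** 2)
    sst = np.sum((obs - obs.mean(axis=0)) ** 2)
    return float(1.0 - sse / sst) if sst > 0 else float("nan")


def compositional_predict(
    points: np.ndarray,
    labels,
    n_boot: int = 10000,
    n_perm: int = 10000,
    seed: int = 0,
    donor_lengths: str = "others",
) -> CompositionalReport:
    """Predict each (length, 1st-consonant) class from the other lengths.

    Each held-out class mean is reconstructed as the sequence-length mean
    plus the like-consonant displacement vector borrowed from donor lengths,
    rescaled by the ratio of mean displacement norms (estimated without the
    held-out class); predictions are averaged when several donor lengths
    exist.  R² is reported for condition averages and for single trials,
    with percentile-bootstrap CIs over pooled predictions and label-shuffle
    permutation p-values (labels shuffled before displacement estimation).
    """
    points = np.asarray(points, dtype=float)
    labels = list(labels)

    def both_r2(pts, labs):
        keys, cmeans, preds = _predict_classes(pts, labs, donor_lengths)
        classes = sorted(cmeans)
        obs_c = np.array([cmeans[c] for c in classes])
        pred_c = np.array([preds[c] for c in classes])
        obs_t = pts
        pred_t = np.array([preds[k] for k in keys])
        return _r2(obs_c, pred_c), _r2(obs_t, pred_t), cmeans, preds, keys

    r2c, r2t, cmeans, preds, keys = both_r2(points, labels)

    rng = np.random.default_rng(seed)
    ci_c = ci_t = None
    if n_boot:
        classes = sorted(cmeans)
        obs_c = np.array([cmeans[c] for c in classes])
        pred_c = np.array([preds[c] for c in classes])
        pred_t = np.array([preds[k] for k in keys])
        nc, nt = len(classes), len(points)
        bc = np.empty(n_boot)
        bt = np.empty(n_boot)
        for i in range(n_boot):
            ic = rng.integers(0, nc, nc)
            it = rng.integers(0, nt, nt)
            bc[i] = _r2(obs_c[ic], pred_c[ic])
            bt[i] = _r2(points[it], pred_t[it])
        ci_c = tuple(np.quantile(bc, [0.025, 0.975]))
        ci_t = tuple(np.quantile(bt, [0.025, 0.975]))

    p_c = p_t = None
    if n_perm:
        null_c = np.empty(n_perm)
        null_t = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(len(labels))
            labs = [labels[j] for j in perm]
            null_c[i], null_t[i], *_ = both_r2(points, labs)
        p_c = float(np.mean(null_c >= r2c))
        p_t = float(np.mean(null_t >= r2t))

    return CompositionalReport(
        r2_condition=r2c, r2_single_trial=r2t,
        ci_condition=ci_c, ci_single_trial=ci_t,
        p_condition=p_c, p_single_trial=p_t, n_perm=n_perm,
        class_means=cmeans, predictions=preds,
    )


# ---------------------------------------------------------------------------
# plane fit and correlation structure
# ---------------------------------------------------------------------------

def plane_variance_2d(points: np.ndarray) -> float:
    """Fraction of variance of a point set captured by its best 2-D plane.

    Mean-centers, takes the top two singular directions, and reports the
    captured variance fraction.  Invariant to rigid rotation.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 3:
        raise DesignError("need at least 3 points")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    total = np.sum(s**2)
    if total == 0:
        return 1.0
    return float(np.sum(s[:2] ** 2) / total)


def marginal_correlation_matrix(
    session: SessionData,
    window: EpochWindow,
    subtract_length_means: bool = False,
) -> pd.DataFrame:
    """Pearson correlations between marginal population vectors.

    One group per (sequence length, position, phoneme): the mean preparatory
    population vector over trials of that length carrying that phoneme at
    that slot.  Rows/columns ordered length -> position -> phoneme.  With
    ``subtract_length_means`` the per-length mean population vector is
    removed from trials first, isolating phoneme structure from the shared
    length offset.  Zero-variance group vectors yield NaN entries.
    """
    ext = extract_windows(session, window, mode="average")
    x = ext.matrix
    labs = [session.labels[i] for i in ext.kept]
    lengths = sorted({lab.length_class for lab in labs if not lab.is_rest})
    if subtract_length_means:
        x = x.copy()
        for L in lengths:
            sel = np.array([lab.length_class == L for lab in labs])
            if sel.any():
                x[sel] -= x[sel].mean(axis=0)
    inventory = (session.condition_set.inventory
                 if session.condition_set is not None
                 else sorted({c for lab in labs for c in lab.consonants}))
    index, vectors = [], []
    for L in lengths:
        for p in range(1, L + 1):
            for tok in inventory:
                sel = np.array([
                    lab.length_class == L and lab.consonant_at(p) == tok
                    for lab in labs
                ])
                if not sel.any():
                    continue
                index.append((L, p, tok))
                vectors.append(x[sel].mean(axis=0))
    v = np.array(vectors)
    sd = v.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(v)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    mi = pd.MultiIndex.from_tuples(index, names=["length", "position",
                                                 "phoneme"])
    return pd.DataFrame(corr, index=mi, columns=mi)
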