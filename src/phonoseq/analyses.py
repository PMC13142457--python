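"""Population decoding experiments.

Per-position pairwise decoding, decoding timecourses, cross-time and
cross-epoch decoder generalization, cross-position generalization,
sequence-length decoding, and the word-boundary analyses.  Every reported
number is computed from held-out scores only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DesignError, EpochError, LabelError
from .lda import (
    cross_validate,
    evaluate,
    fit_diag_lda,
    binary_discriminant,
    loo_binary_scores,
    rank_auc,
    stratified_folds,
)
from .preprocess import (
    EpochWindow,
    PREP_05,
    PREP_06,
    PREP_07,
    PREP_08,
    extract_windows,
)
from .session import SessionData
from .task import late_position_pair_contexts, single_position_pairs


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _session_pairs(session: SessionData, position: int, min_trials: int = 2):
    """Single-position-difference pairs with enough trials in the session."""
    if session.condition_set is None:
        raise DesignError("session carries no condition set")
    keys = session.label_keys
    counts = pd.Series(keys).value_counts().to_dict()
    pairs = []
    for a, b in single_position_pairs(session.condition_set, position):
        if counts.get(a.key, 0) >= min_trials and \
                counts.get(b.key, 0) >= min_trials:
            pairs.append((a, b))
    if not pairs:
        raise DesignError(f"no decodable pairs at position {position}")
    return pairs


def _pair_xy(matrix, keys, pair):
    a, b = pair
    sel = np.flatnonzero((keys == a.key) | (keys == b.key))
    y = (keys[sel] == b.key).astype(int)
    return matrix[sel], y, sel


# ---------------------------------------------------------------------------
# pairwise position decoding
# ---------------------------------------------------------------------------

@dataclass
class PairwiseDecodingResult:
    position: int
    mean_auc: float
    ci: tuple[float, float]
    p_value: float
    per_pair: pd.DataFrame
    n_pairs: int
    window: EpochWindow


def pairwise_position_decoding(
    session: SessionData,
    position: int,
    window: EpochWindow = PREP_08,
    n_boot: int = 10000,
    seed: int = 0,
) -> PairwiseDecodingResult:
    """Binary diagonal-LDA decoding of every single-position pair.

    One leave-one-out decoder per condition pair on window-averaged
    activity; AUC pooled over held-out trials per pair, averaged over
    pairs.  The CI is a percentile bootstrap over per-pair AUCs and the
    p-value a one-sided one-sample t-test of per-pair AUCs against 0.5
    (family-level FDR is applied by the caller across positions/arrays).
    """
    pairs = _session_pairs(session, position)
    ext = extract_windows(session, window, mode="average")
    keys = session.label_keys[ext.kept]
    rows = []
    for a, b in pairs:
        x, y, _ = _pair_xy(ext.matrix, keys, (a, b))
        probs = loo_binary_scores(x, y)
        rows.append({
            "pair": f"{a.key} vs {b.key}",
            "auc": rank_auc(probs, y == 1),
            "n_trials": len(y),
        })
    per_pair = pd.DataFrame(rows)
    aucs = per_pair["auc"].to_numpy()
    rng = np.random.default_rng(seed)
    boot = rng.choice(aucs, size=(n_boot, len(aucs))).mean(axis=1) \
        if len(aucs) > 1 else np.repeat(aucs.mean(), n_boot)
    ci = tuple(np.quantile(boot, [0.025, 0.975]))
    if len(aucs) > 1 and np.ptp(aucs) > 0:
        p = float(sps.ttest_1samp(aucs, 0.5, alternative="greater").pvalue)
    else:
        p = float("nan")
    return PairwiseDecodingResult(
        position=position, mean_auc=float(aucs.mean()), ci=ci, p_value=p,
        per_pair=per_pair, n_pairs=len(aucs), window=window,
    )


@dataclass
class DecodingTimecourse:
    position: int
    times: np.ndarray               # window-start offsets (s) from the event
    mean_auc: np.ndarray
    window: EpochWindow
    n_pairs: int


def pairwise_decoding_timecourse(
    session: SessionData,
    position: int,
    window: EpochWindow,
    width_ms: float = 100.0,
    step_ms: float = 60.0,
) -> DecodingTimecourse:
    """Within-window pairwise decoding swept along a sliding grid."""
    pairs = _session_pairs(session, position)
    ext = extract_windows(session, window, mode="sliding",
                          width_ms=width_ms, step_ms=step_ms)
    keys = session.label_keys[ext.kept]
    n_t = len(ext.times)
    total = np.zeros(n_t)
    for pair in pairs:
        x, y, _ = _pair_xy(ext.matrix, keys, pair)
        for t in range(n_t):
            probs = loo_binary_scores(x[:, t, :], y)
            total[t] += rank_auc(probs, y == 1)
    return DecodingTimecourse(
        position=position, times=ext.times, mean_auc=total / len(pairs),
        window=window, n_pairs=len(pairs),
    )


# ---------------------------------------------------------------------------
# cross-time generalization
# ---------------------------------------------------------------------------

DEFAULT_EPOCH_WINDOWS = {
    "cue": EpochWindow("cue_onset", 0.0, 1.4),
    "prep": PREP_08,
    "speech": EpochWindow("speech_onset", -0.5, 0.5),
}


@dataclass
class TimeGeneralizationMatrix:
    position: int
    fit_times: list                  # [(epoch, start_offset_s), ...]
    auc: np.ndarray                  # (T, T): fit x test
    n_trials: np.ndarray             # trials available per fit time
    mask: np.ndarray                 # fit times meeting the min-trials rule
    min_trials: int
    n_pairs: int

    def diagonal(self) -> np.ndarray:
        return np.diag(self.auc)


def cross_time_generalization(
    session: SessionData,
    position: int,
    epoch_windows: dict | None = None,
    width_ms: float = 100.0,
    step_ms: float = 60.0,
    min_trials: int = 900,
) -> TimeGeneralizationMatrix:
    """Fit-time x test-time decoder generalization across trial epochs.

    For each pair and fit time a leave-one-out binary decoder is fit; each
    held-out trial is scored at every test time, AUC pooled per (fit, test)
    and averaged over pairs.  Fit times with fewer than ``min_trials``
    available trials are flagged in the mask, which is reported rather than
    silently applied.
    """
    windows = epoch_windows or DEFAULT_EPOCH_WINDOWS
    pairs = _session_pairs(session, position)
    exts = {}
    common = None
    for epoch, win in windows.items():
        exts[epoch] = extract_windows(session, win, mode="sliding",
                                      width_ms=width_ms, step_ms=step_ms)
        kept = set(exts[epoch].kept.tolist())
        common = kept if common is None else (common & kept)
    common = np.array(sorted(common))
    fit_times = []
    blocks = []
    for epoch in windows:
        ext = exts[epoch]
        sel = np.searchsorted(ext.kept, common)
        blocks.append(ext.matrix[sel])
        fit_times.extend((epoch, float(t)) for t in ext.times)
    data = np.concatenate(blocks, axis=1)       # (n, T, F)
    keys = session.label_keys[common]
    n_t = data.shape[1]
    total = np.zeros((n_t, n_t))
    trial_count = np.zeros(n_t)
    for pair in pairs:
        x, y, _ = _pair_xy(data, keys, pair)
        trial_count += len(y)
        for t in range(n_t):
            probs = loo_binary_scores(x[:, t, :], y, X_eval=x)
            for u in range(n_t):
                total[t, u] += rank_auc(probs[:, u], y == 1)
    auc = total / len(pairs)
    return TimeGeneralizationMatrix(
        position=position, fit_times=fit_times, auc=auc,
        n_trials=trial_count, mask=trial_count >= min_trials,
        min_trials=min_trials, n_pairs=len(pairs),
    )


# ---------------------------------------------------------------------------
# cross-epoch generalization
# ---------------------------------------------------------------------------

@dataclass
class CrossEpochResult:
    position: int
    peak_times: dict                 # epoch -> window-center offset (s)
    auc: dict                        # {"cue", "prep", "speech"} -> mean AUC
    per_pair: pd.DataFrame
    prep_window: EpochWindow


def cross_epoch_generalization(
    session: SessionData,
    position: int,
    sweep_windows: dict | None = None,
    width_ms: float = 100.0,
    step_ms: float = 60.0,
    window_s: float = 0.5,
) -> CrossEpochResult:
    """Decoders trained on cue-epoch activity, tested on all three epochs.

    Peak decoding times are found by a within-window sweep in the cue and
    speech epochs (first bin on ties); three 0.5 s windows are then built —
    cue and speech centered on their peaks, preparation the 0.5 s before
    the go cue — and a leave-one-out decoder trained on the cue window is
    evaluated on each held-out trial's three epoch vectors.
    """
    sweeps = sweep_windows or {
        "cue": DEFAULT_EPOCH_WINDOWS["cue"],
        "speech": DEFAULT_EPOCH_WINDOWS["speech"],
    }
    for name in ("cue", "speech"):
        if name not in sweeps:
            raise EpochError(f"sweep window for epoch {name!r} missing")
    half = window_s / 2
    peak_times = {}
    for epoch, win in sweeps.items():
        tc = pairwise_decoding_timecourse(
            session, position, win, width_ms=width_ms, step_ms=step_ms
        )
        i = int(np.argmax(tc.mean_auc))       # first max on ties
        center = float(tc.times[i] + width_ms / 2000.0)
        # keep the peak-centered window inside the swept epoch range
        lo, hi = win.start_s + half, win.end_s - half
        peak_times[epoch] = min(max(center, lo), hi) if lo < hi else center
    cue_win = EpochWindow("cue_onset", peak_times["cue"] - half,
                          peak_times["cue"] + half)
    speech_win = EpochWindow("speech_onset", peak_times["speech"] - half,
                             peak_times["speech"] + half)
    prep_win = EpochWindow("go_cue", -window_s, 0.0)

    ext_c = extract_windows(session, cue_win, mode="average")
    ext_p = extract_windows(session, prep_win, mode="average",
                            trials=ext_c.kept)
    ext_s = extract_windows(session, speech_win, mode="average",
                            trials=ext_c.kept)
    if not (np.array_equal(ext_c.kept, ext_p.kept)
            and np.array_equal(ext_c.kept, ext_s.kept)):
        raise EpochError("epoch windows cover different trial subsets")
    keys = session.label_keys[ext_c.kept]
    stack = np.stack([ext_c.matrix, ext_p.matrix, ext_s.matrix], axis=1)

    pairs = _session_pairs(session, position)
    rows = []
    for a, b in pairs:
        sel = np.flatnonzero((keys == a.key) | (keys == b.key))
        y = (keys[sel] == b.key).astype(int)
        probs = loo_binary_scores(stack[sel, 0, :], y, X_eval=stack[sel])
        rows.append({
            "pair": f"{a.key} vs {b.key}",
            "cue": rank_auc(probs[:, 0], y == 1),
            "prep": rank_auc(probs[:, 1], y == 1),
            "speech": rank_auc(probs[:, 2], y == 1),
        })
    per_pair = pd.DataFrame(rows)
    return CrossEpochResult(
        position=position, peak_times=peak_times,
        auc={k: float(per_pair[k].mean()) for k in ("cue", "prep", "speech")},
        per_pair=per_pair, prep_window=prep_win,
    )


# ---------------------------------------------------------------------------
# cross-position generalization
# ---------------------------------------------------------------------------

@dataclass
class GeneralizationResult:
    train_position: int
    test_position: int
    auc_within: float
    auc_cross: float
    normalized_generalization: float
    ci: tuple[float, float] | None
    n_trials: int


def _ovr_auc(scores: np.ndarray, y, classes) -> float:
    return float(np.mean([
        rank_auc(scores[:, j], np.asarray(y) == c)
        for j, c in enumerate(classes)
    ]))


def cross_position_generalization(
    session: SessionData,
    train_position: int,
    test_position: int,
    window: EpochWindow = PREP_07,
    k: int = 5,
    seed: int = 0,
    n_boot: int = 10000,
) -> GeneralizationResult:
    """Does a decoder of one position's consonant read out another position?

    A multiclass diagonal-LDA is trained on ``train_position`` labels with
    stratified 5-fold CV; held-out scores are evaluated both against the
    training-position labels (in-context, one-vs-rest AUC averaged over the
    inventory) and relabeled with the ``test_position`` identity
    (out-of-context).  Normalized generalization is
    (AUC_cross - 0.5)/(AUC_within - 0.5), with a bootstrap CI over held-out
    trials only.
    """
    need = max(train_position, test_position)
    idx = np.array([i for i, lab in enumerate(session.labels)
                    if not lab.is_rest and lab.length_class >= need])
    if idx.size == 0:
        raise DesignError("no trials cover both positions")
    ext = extract_windows(session, window, mode="average", trials=idx)
    labs = [session.labels[i] for i in ext.kept]
    y_train = np.array([lab.consonant_at(train_position) for lab in labs])
    y_test = np.array([lab.consonant_at(test_position) for lab in labs])
    if set(y_train) != set(y_test):
        raise LabelError("consonant inventories differ across positions")
    strata = np.array([lab.key for lab in labs])
    scores, classes = cross_validate(
        ext.matrix, y_train, strategy="stratified", k=k, seed=seed,
        strata=strata,
    )
    auc_w = _ovr_auc(scores, y_train, classes)
    auc_x = _ovr_auc(scores, y_test, classes)

    def norm_gen(aw, ax):
        return (ax - 0.5) / (aw - 0.5) if aw != 0.5 else float("nan")

    ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        n = len(y_train)
        draws = np.empty(n_boot)
        for i in range(n_boot):
            b = rng.integers(0, n, n)
            if len(set(y_train[b])) < len(classes) or \
                    len(set(y_test[b])) < len(classes):
                draws[i] = np.nan
                continue
            draws[i] = norm_gen(_ovr_auc(scores[b], y_train[b], classes),
                                _ovr_auc(scores[b], y_test[b], classes))
        ci = tuple(np.nanquantile(draws, [0.025, 0.975]))
    return GeneralizationResult(
        train_position=train_position, test_position=test_position,
        auc_within=auc_w, auc_cross=auc_x,
        normalized_generalization=norm_gen(auc_w, auc_x),
        ci=ci, n_trials=len(y_train),
    )


# ---------------------------------------------------------------------------
# sequence-length decoding
# ---------------------------------------------------------------------------

@dataclass
class LengthDecodingResult:
    normalized_balanced_accuracy: float
    balanced_accuracy: float
    chance: float
    p_value: float | None
    ci: tuple[float, float] | None
    confusion: np.ndarray
    classes: np.ndarray
    n_perm: int


def sequence_length_decoding(
    session: SessionData,
    window: EpochWindow = PREP_06,
    k: int = 5,
    n_perm: int = 10000,
    seed: int = 0,
    n_boot: int = 10000,
) -> LengthDecodingResult:
    """Multiclass decoding of sequence-length class from preparatory activity.

    Stratified k-fold diagonal LDA on length labels; performance is the
    normalized balanced accuracy (BA - chance)/(1 - chance) with chance
    1/K.  The permutation test reruns the full cross-validation on shuffled
    labels, p = fraction of null draws >= observed (one-tailed).
    """
    idx = np.array([i for i, lab in enumerate(session.labels)
                    if not lab.is_rest])
    ext = extract_windows(session, window, mode="average", trials=idx)
    labs = [session.labels[i] for i in ext.kept]
    y = np.array([lab.length_class for lab in labs])
    if len(set(y)) < 2:
        raise DesignError("need >= 2 sequence-length classes")
    strata = np.array([lab.key for lab in labs])

    def run_cv(labels_arr):
        scores, classes = cross_validate(
            ext.matrix, labels_arr, strategy="stratified", k=k, seed=seed,
            strata=strata,
        )
        return evaluate(scores, labels_arr, mode="multiclass",
                        classes=classes)

    res = run_cv(y)
    rng = np.random.default_rng(seed)
    p = None
    if n_perm:
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = run_cv(rng.permutation(y)) \
                .normalized_balanced_accuracy
        p = float(np.mean(null >= res.normalized_balanced_accuracy))
    ci = None
    if n_boot:
        scores, classes = cross_validate(
            ext.matrix, y, strategy="stratified", k=k, seed=seed,
            strata=strata,
        )
        n = len(y)
        draws = np.empty(n_boot)
        for i in range(n_boot):
            b = rng.integers(0, n, n)
            if len(set(y[b])) < len(classes):
                draws[i] = np.nan
                continue
            draws[i] = evaluate(scores[b], y[b], mode="multiclass",
                                classes=classes) \
                .normalized_balanced_accuracy
        ci = tuple(np.nanquantile(draws, [0.025, 0.975]))
    return LengthDecodingResult(
        normalized_balanced_accuracy=res.normalized_balanced_accuracy,
        balanced_accuracy=res.balanced_accuracy,
        chance=res.chance, p_value=p, ci=ci,
        confusion=res.confusion, classes=res.classes, n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# word-boundary analyses
# ---------------------------------------------------------------------------

@dataclass
class WordBoundaryResult:
    boundary_auc: float
    boundary_ci: tuple[float, float]
    boundary_p: float
    boundary_fold_aucs: np.ndarray
    one_word_auc: float
    two_word_auc: float
    delta_auc: float                 # two-word minus one-word
    delta_p: float
    one_word_pair_aucs: np.ndarray
    two_word_pair_aucs: np.ndarray
    one_word_p: float
    two_word_p: float


def word_boundary_analysis(
    session: SessionData,
    window: EpochWindow = PREP_05,
    k: int = 10,
    seed: int = 0,
    shared_slots: int = 2,
) -> WordBoundaryResult:
    """Word-boundary decoding and late-position truncation analysis.

    (a) An LDA classifier decodes one- vs two-word segmentation from the
    preparatory window, stratified k-fold over phoneme sequences; AUC is
    averaged across folds with a normal-approximation CI
    (±1.96 x sd over folds) and a one-sided fold-level t-test vs 0.5.

    (b) For every pair of conditions sharing the first ``shared_slots``
    consonants and differing later, binary leave-one-out decoders are fit
    separately within the one-word and two-word contexts; per-context mean
    AUC and the one-sided two-sample t-test on the pair-level difference
    (one-word > two-word) quantify plan truncation at the boundary.
    """
    if session.condition_set is None:
        raise DesignError("session carries no condition set")
    segs = {c.segmentation for c in session.condition_set.conditions
            if not c.is_rest}
    if () not in segs or len(segs) < 2:
        raise DesignError("session is not built on a word-boundary set")

    ext = extract_windows(session, window, mode="average")
    labs = [session.labels[i] for i in ext.kept]
    keys = np.array([lab.key for lab in labs])
    y = np.array([lab.n_words for lab in labs])
    seq = np.array(["-".join(lab.consonants) for lab in labs])
    folds = stratified_folds(y, k, seed=seed, strata=seq)
    fold_aucs = []
    for tr, te in folds:
        model = fit_diag_lda(ext.matrix[tr], y[tr])
        _, prob = binary_discriminant(model, ext.matrix[te])
        fold_aucs.append(rank_auc(prob, y[te] == 2))
    fold_aucs = np.array(fold_aucs)
    b_auc = float(fold_aucs.mean())
    b_ci = (b_auc - 1.96 * fold_aucs.std(ddof=1),
            b_auc + 1.96 * fold_aucs.std(ddof=1))
    b_p = float(sps.ttest_1samp(fold_aucs, 0.5,
                                alternative="greater").pvalue)

    contexts = late_position_pair_contexts(session.condition_set,
                                           shared_slots=shared_slots)
    counts = pd.Series(keys).value_counts().to_dict()

    def context_aucs(seg_key):
        aucs = []
        for a, b in contexts.get(seg_key, []):
            if counts.get(a.key, 0) < 2 or counts.get(b.key, 0) < 2:
                continue
            x, yy, _ = _pair_xy(ext.matrix, keys, (a, b))
            probs = loo_binary_scores(x, yy)
            aucs.append(rank_auc(probs, yy == 1))
        return np.array(aucs)

    two_seg = sorted(s for s in segs if s)[0]
    one_aucs = context_aucs(())
    two_aucs = context_aucs(two_seg)
    if one_aucs.size == 0 or two_aucs.size == 0:
        raise DesignError("no matched late-position pairs in both contexts")
    one_p = float(sps.ttest_1samp(one_aucs, 0.5,
                                  alternative="greater").pvalue)
    two_p = float(sps.ttest_1samp(two_aucs, 0.5,
                                  alternative="greater").pvalue)
    delta_p = float(sps.ttest_ind(one_aucs, two_aucs, equal_var=False,
                                  alternative="greater").pvalue)
    return WordBoundaryResult(
        boundary_auc=b_auc, boundary_ci=b_ci, boundary_p=b_p,
        boundary_fold_aucs=fold_aucs,
        one_word_auc=float(one_aucs.mean()),
        two_word_auc=float(two_aucs.mean()),
        delta_auc=float(two_aucs.mean() - one_aucs.mean()),
        delta_p=delta_p,
        one_word_pair_aucs=one_aucs, two_word_pair_aucs=two_aucs,
        one_word_p=one_p, two_word_p=two_p,
    )
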