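"""Position-specific linear encoding model of phoneme sequences.

Activity y for a sequence with phonemes (p₁..p_S) is modeled as
y = β₀ + p₁ᵀβ₁ + ... + p_Sᵀβ_S + ε with one-hot phoneme indicators per
slot, fit feature-wise by closed-form ridge regression (intercept
unpenalized).  The one-hot + intercept design is rank deficient; the ridge
penalty resolves the gauge so each slot's coefficient block is zero-sum —
the same identifiability convention the synthetic generator uses, which is
what makes coefficient recovery well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import FoldError, LabelError, ShapeError
from .lda import stratified_folds
from .task import ConditionLabel


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class EncodingDesign:
    matrix: np.ndarray                   # (n, S*m + 1), intercept last
    columns: list                        # [(slot, phoneme), ..., "intercept"]
    inventory: tuple[str, ...]
    n_slots: int
    labels: tuple[ConditionLabel, ...]

    @property
    def n_predictors(self) -> int:
        return self.matrix.shape[1] - 1

    def condition_keys(self) -> np.ndarray:
        return np.array([lab.key for lab in self.labels])


def build_design_matrix(labels, inventory, n_slots: int) -> EncodingDesign:
    """One-hot phoneme-at-slot design, slot-major in inventory order.

    Rows for labels shorter than ``n_slots`` leave the uncovered slot
    blocks at zero; the intercept column is last.
    """
    inventory = tuple(inventory)
    labels = tuple(labels)
    lut = {tok: j for j, tok in enumerate(inventory)}
    m = len(inventory)
    x = np.zeros((len(labels), n_slots * m + 1))
    for i, lab in enumerate(labels):
        if lab.length_class > n_slots:
            raise LabelError(
                f"label {lab.key!r} longer than the {n_slots}-slot design"
            )
        for p in range(1, lab.length_class + 1):
            tok = lab.consonant_at(p)
            if tok not in lut:
                raise LabelError(f"unknown phoneme {tok!r}")
            x[i, (p - 1) * m + lut[tok]] = 1.0
    x[:, -1] = 1.0
    columns = [(p, tok) for p in range(1, n_slots + 1) for tok in inventory]
    columns.append("intercept")
    return EncodingDesign(
        matrix=x, columns=columns, inventory=inventory,
        n_slots=n_slots, labels=labels,
    )


# ---------------------------------------------------------------------------
# ridge fit + validation
# ---------------------------------------------------------------------------

@dataclass
class EncodingModel:
    intercept: np.ndarray                # (F,)
    coefficients: np.ndarray             # (F, S*m) slot-major
    columns: list
    inventory: tuple[str, ...]
    n_slots: int
    alpha: float
    residual_variance: np.ndarray | None = None
    feature_mask: np.ndarray | None = None

    def coefficient_vector(self, slot: int, phoneme: str) -> np.ndarray:
        j = self.columns.index((slot, phoneme))
        return self.coefficients[:, j]

    def predict(self, design: EncodingDesign) -> np.ndarray:
        beta = np.vstack([self.coefficients.T, self.intercept[None, :]])
        return design.matrix @ beta


def _ridge_fit(x: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Closed-form multi-output ridge, last (intercept) column unpenalized."""
    k = x.shape[1]
    pen = np.full(k, alpha)
    pen[-1] = 0.0
    a = x.T @ x + np.diag(pen)
    return np.linalg.solve(a, x.T @ y)


@dataclass
class EncodingReport:
    r2_single_trial: float
    r2_condition: float
    ci_single_trial: tuple[float, float] | None
    ci_condition: tuple[float, float] | None
    p_single_trial: float | None
    p_condition: float | None
    n_perm: int
    predictions: np.ndarray
    group_keys: np.ndarray


def _uniform_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    """Per-feature R² averaged uniformly (each electrode weighted equally)."""
    sse = np.sum((obs - pred) ** 2, axis=0)
    sst = np.sum((obs - obs.mean(axis=0)) ** 2, axis=0)
    ok = sst > 0
    if not ok.any():
        return float("nan")
    return float(np.mean(1.0 - sse[ok] / sst[ok]))


def _marginal_group_keys(labels, marginalize_slot: int = 1) -> np.ndarray:
    keys = []
    for lab in labels:
        keys.append("/".join(
            tok for p, tok in enumerate(lab.consonants, start=1)
            if p != marginalize_slot
        ))
    return np.array(keys)


def _group_means(y: np.ndarray, keys: np.ndarray):
    uniq = np.unique(keys)
    return np.array([y[keys == k].mean(axis=0) for k in uniq]), uniq


def _cv_predictions(design, y, alpha, n_splits, seed):
    folds = stratified_folds(
        np.zeros(len(y)), n_splits, seed=seed,
        strata=design.condition_keys(),
    )
    pred = np.full_like(y, np.nan)
    for tr, te in folds:
        if len(te) == 0:
            raise FoldError("empty validation fold")
        beta = _ridge_fit(design.matrix[tr], y[tr], alpha)
        pred[te] = design.matrix[te] @ beta
    return pred


def fit_and_validate(
    design: EncodingDesign,
    Y: np.ndarray,
    alpha: float = 0.5,
    n_splits: int = 3,
    seed: int = 0,
    n_boot: int = 10000,
    n_perm: int = 10000,
    marginalize_slot: int = 1,
) -> tuple[EncodingModel, EncodingReport]:
    """Cross-validated ridge encoding fit with pooled held-out R².

    Folds are stratified by condition.  ``r2_single_trial`` averages
    per-feature held-out R² uniformly over features; ``r2_condition`` is the
    same statistic on condition means after marginalizing the
    ``marginalize_slot`` position (groups defined by the remaining slots).
    Bootstrap CIs resample the pooled predictions; permutation p-values
    reshuffle condition labels and rerun the full cross-validation.
    """
    y = np.asarray(Y, dtype=float)
    if y.ndim != 2 or y.shape[0] != design.matrix.shape[0]:
        raise ShapeError("Y must be trials x features matching the design")

    pred = _cv_predictions(design, y, alpha, n_splits, seed)
    gkeys = _marginal_group_keys(design.labels, marginalize_slot)
    r2_trial = _uniform_r2(y, pred)
    gy, uniq = _group_means(y, gkeys)
    gp, _ = _group_means(pred, gkeys)
    r2_cond = _uniform_r2(gy, gp)

    rng = np.random.default_rng(seed)
    ci_t = ci_c = None
    if n_boot:
        n = len(y)
        bt = np.empty(n_boot)
        bc = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            bt[i] = _uniform_r2(y[idx], pred[idx])
            gyb, _ = _group_means(y[idx], gkeys[idx])
            gpb, _ = _group_means(pred[idx], gkeys[idx])
            bc[i] = _uniform_r2(gyb, gpb)
        ci_t = tuple(np.quantile(bt, [0.025, 0.975]))
        ci_c = tuple(np.quantile(bc, [0.025, 0.975]))

    p_t = p_c = None
    if n_perm:
        null_t = np.empty(n_perm)
        null_c = np.empty(n_perm)
        labels = list(design.labels)
        for i in range(n_perm):
            perm = rng.permutation(len(labels))
            d_perm = build_design_matrix(
                [labels[j] for j in perm], design.inventory, design.n_slots
            )
            pp = _cv_predictions(d_perm, y, alpha, n_splits, seed)
            null_t[i] = _uniform_r2(y, pp)
            gk = _marginal_group_keys(d_perm.labels, marginalize_slot)
            gyp, _ = _group_means(y, gk)
            gpp, _ = _group_means(pp, gk)
            null_c[i] = _uniform_r2(gyp, gpp)
        p_t = float(np.mean(null_t >= r2_trial))
        p_c = float(np.mean(null_c >= r2_cond))

    beta = _ridge_fit(design.matrix, y, alpha)
    model = EncodingModel(
        intercept=beta[-1],
        coefficients=beta[:-1].T,
        columns=design.columns[:-1],
        inventory=design.inventory,
        n_slots=design.n_slots,
        alpha=alpha,
        residual_variance=np.var(y - design.matrix @ beta, axis=0),
    )
    report = EncodingReport(
        r2_single_trial=r2_trial, r2_condition=r2_cond,
        ci_single_trial=ci_t, ci_condition=ci_c,
        p_single_trial=p_t, p_condition=p_c, n_perm=n_perm,
        predictions=pred, group_keys=gkeys,
    )
    return model, report


# ---------------------------------------------------------------------------
# coefficient similarity
# ---------------------------------------------------------------------------

@dataclass
class CosineSimilarityReport:
    matrix: pd.DataFrame                       # (slot, phoneme) x same
    position_pair_summary: dict                # (p, p') -> mean cosine
    position_pair_p: dict | None
    position_pair_ci: dict | None
    n_perm: int


def _cosine_matrix(model: EncodingModel) -> pd.DataFrame:
    cols = model.columns
    b = model.coefficients                     # (F, S*m)
    norms = np.linalg.norm(b, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (b.T @ b) / np.outer(norms, norms)
    cos[norms == 0, :] = np.nan
    cos[:, norms == 0] = np.nan
    mi = pd.MultiIndex.from_tuples(cols, names=["position", "phoneme"])
    return pd.DataFrame(cos, index=mi, columns=mi)


def _pair_summaries(matrix: pd.DataFrame, n_slots: int, inventory):
    out = {}
    for p in range(1, n_slots + 1):
        for q in range(p + 1, n_slots + 1):
            vals = [matrix.loc[(p, tok), (q, tok)] for tok in inventory]
            out[(p, q)] = float(np.nanmean(vals))
    return out


def coefficient_similarity(
    design: EncodingDesign,
    Y: np.ndarray,
    alpha: float = 0.5,
    n_perm: int = 10000,
    n_boot: int = 10000,
    seed: int = 0,
) -> tuple[EncodingModel, CosineSimilarityReport]:
    """Cosine structure of encoding coefficients across positions.

    Refits the ridge model on all trials, computes the full cosine matrix
    over (slot, phoneme) coefficient vectors, and summarizes each position
    pair as the mean cosine between like-phoneme vectors.  Permutation
    p-values shuffle condition labels and refit; bootstrap CIs resample
    trials and refit.
    """
    if design.n_slots < 2:
        raise LabelError("coefficient similarity needs >= 2 slots")
    y = np.asarray(Y, dtype=float)
    beta = _ridge_fit(design.matrix, y, alpha)
    model = EncodingModel(
        intercept=beta[-1], coefficients=beta[:-1].T,
        columns=design.columns[:-1], inventory=design.inventory,
        n_slots=design.n_slots, alpha=alpha,
    )
    matrix = _cosine_matrix(model)
    summary = _pair_summaries(matrix, design.n_slots, design.inventory)

    rng = np.random.default_rng(seed)
    pair_p = pair_ci = None

    def refit_summary(x_mat):
        b = _ridge_fit(x_mat, y, alpha)
        m = EncodingModel(
            intercept=b[-1], coefficients=b[:-1].T,
            columns=design.columns[:-1], inventory=design.inventory,
            n_slots=design.n_slots, alpha=alpha,
        )
        return _pair_summaries(_cosine_matrix(m), design.n_slots,
                               design.inventory)

    if n_perm:
        null = {k: np.empty(n_perm) for k in summary}
        for i in range(n_perm):
            perm = rng.permutation(len(y))
            s = refit_summary(design.matrix[perm])
            for k in summary:
                null[k][i] = s[k]
        pair_p = {k: float(np.mean(null[k] >= summary[k])) for k in summary}

    if n_boot:
        draws = {k: np.empty(n_boot) for k in summary}
        n = len(y)
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            b = _ridge_fit(design.matrix[idx], y[idx], alpha)
            m = EncodingModel(
                intercept=b[-1], coefficients=b[:-1].T,
                columns=design.columns[:-1], inventory=design.inventory,
                n_slots=design.n_slots, alpha=alpha,
            )
            s = _pair_summaries(_cosine_matrix(m), design.n_slots,
                                design.inventory)
            for k in summary:
                draws[k][i] = s[k]
        pair_ci = {
            k: tuple(np.quantile(draws[k], [0.025, 0.975])) for k in summary
        }

    report = CosineSimilarityReport(
        matrix=matrix, position_pair_summary=summary,
        position_pair_p=pair_p, position_pair_ci=pair_ci, n_perm=n_perm,
    )
    return model, report
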