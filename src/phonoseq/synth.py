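"""Synthetic session generator with a known compositional ground truth.

The generator emulates instructed-delay speech-preparation sessions: 20 ms
binned threshold-crossing counts and spike-band power on a 64-electrode
array, trials with cue-listening / preparatory-delay / attempted-speech
epochs, and condition labels from full-factorial consonant-sequence designs.

The latent code is linear and compositional: the mean activity for a
condition is the sum of position-specific phoneme vectors (with controllable
cross-position cosine alignment and position-dependent gains), a sequence
length axis, a word-boundary axis, and word-boundary truncation of
post-boundary slots during preparation.  Every vector of the code is stored,
so each downstream analysis can be validated by parameter recovery.

Geometry construction: phonemes within a position sit at the vertices of a
regular simplex (zero-sum, mutually equidistant); each position maps that
simplex into the feature space through a block-orthonormal frame whose
cross-position inner products realize the requested cosine matrix exactly
(shared-component + orthogonal-residual construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConstructionError, LabelError
from .session import SessionData
from .task import ConditionLabel, ConditionSet

SIGNAL_EPOCHS = ("cue", "prep", "speech")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a simulated session.

    ``n_features`` counts the concatenated feature streams (threshold
    crossings + spike-band power), i.e. two per electrode: 128 for a
    64-electrode array.  ``snr`` is the norm of a per-position phoneme
    pattern divided by the trial-level noise standard deviation — the noise
    floor that survives window averaging.  Per-bin measurement noise is
    additionally drawn independently for each feature stream.
    """

    n_features: int = 128
    snr: float = 2.0
    noise_model: str = "gaussian"  # gaussian | poisson-count
    drift_sd: float = 0.2
    bin_ms: float = 20.0
    seed: int = 0
    trial_noise_sd: float = 1.0
    bin_noise_sd: float = 1.0
    poisson_base_rate: float = 4.0

    def __post_init__(self):
        if self.snr < 0:
            raise ConstructionError("snr must be >= 0")
        if self.bin_ms <= 0:
            raise ConstructionError("bin_ms must be > 0")
        if self.n_features % 2:
            raise ConstructionError(
                "n_features must be even (two streams per electrode)"
            )
        if self.noise_model not in ("gaussian", "poisson-count"):
            raise ConstructionError(
                f"unknown noise model {self.noise_model!r}"
            )

    @property
    def n_electrodes(self) -> int:
        return self.n_features // 2

    @property
    def bin_s(self) -> float:
        return self.bin_ms / 1000.0


def default_position_gains(n_positions: int) -> np.ndarray:
    """Position-dependent gain: tuning weakens for deeper sequence slots."""
    return np.maximum(1.0 - 0.1 * np.arange(n_positions), 0.5)


def default_alignment(n_positions: int, c: float = 0.6) -> np.ndarray:
    """Uniform cross-position cosine target with unit diagonal."""
    a = np.full((n_positions, n_positions), float(c))
    np.fill_diagonal(a, 1.0)
    return a


def _simplex_vertices(m: int) -> np.ndarray:
    """m unit vectors in R^(m-1): zero-sum, equidistant, cosine -1/(m-1)."""
    if m == 1:
        return np.zeros((1, 0))
    centered = np.eye(m) - 1.0 / m
    u, s, _ = np.linalg.svd(centered)
    coords = u[:, : m - 1] * s[: m - 1]
    norms = np.linalg.norm(coords, axis=1, keepdims=True)
    return coords / norms


# ---------------------------------------------------------------------------
# ground-truth code
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthCode:
    """The generator's latent linear code, in electrode (latent) space.

    ``phoneme_vectors[p][token]`` is the per-electrode pattern added when
    ``token`` occupies 1-based slot ``p``; within each position the vectors
    sum to zero (identifiability under a one-hot + intercept model).
    ``boundary_gain`` multiplies post-boundary slots during the preparatory
    epoch only, modeling truncation of the plan at the first word boundary.
    """

    baseline: np.ndarray
    phoneme_vectors: dict[int, dict[str, np.ndarray]]
    position_gains: np.ndarray
    alignment: np.ndarray
    length_axis: np.ndarray
    boundary_axis: np.ndarray
    boundary_gain: float
    epoch_gains: dict[str, float]
    epoch_private: dict[str, dict[int, dict[str, np.ndarray]]] | None
    inventory: tuple[str, ...]
    conjunctive_means: dict[str, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_latent(self) -> int:
        return self.baseline.shape[0]

    @property
    def n_positions(self) -> int:
        return len(self.position_gains)

    def latent_mean(self, label: ConditionLabel, epoch: str) -> np.ndarray:
        """Mean latent (per-electrode) activity for a condition in an epoch."""
        mean = self.baseline.copy()
        if label.is_rest or epoch not in SIGNAL_EPOCHS:
            return mean
        e = self.epoch_gains.get(epoch, 0.0)
        boundary = label.segmentation[0] if label.segmentation else None
        if self.conjunctive_means is not None:
            mean += e * self.conjunctive_means[label.key]
        else:
            for p in range(1, label.length_class + 1):
                w = self.position_gains[p - 1]
                if epoch == "prep" and boundary is not None and p > boundary:
                    w = w * self.boundary_gain
                mean += e * w * self.phoneme_vectors[p][label.consonant_at(p)]
        mean += self.length_axis * label.length_class
        if boundary is not None:
            mean += self.boundary_axis
        if self.epoch_private is not None and epoch in self.epoch_private:
            priv = self.epoch_private[epoch]
            for p in range(1, label.length_class + 1):
                w = self.position_gains[p - 1]
                if epoch == "prep" and boundary is not None and p > boundary:
                    w = w * self.boundary_gain
                mean += w * priv[p][label.consonant_at(p)]
        return mean

    def feature_mean(self, label: ConditionLabel, epoch: str) -> np.ndarray:
        """Mean in concatenated feature space (both streams read one latent)."""
        lat = self.latent_mean(label, epoch)
        return np.concatenate([lat, lat])


def make_ground_truth_code(
    config: GeneratorConfig,
    cset: ConditionSet,
    alignment=None,
    gains=None,
    *,
    length_scale: float = 1.0,
    boundary_scale: float = 1.5,
    boundary_gain: float = 1.0,
    epoch_gains: dict[str, float] | None = None,
    epoch_private_scale: float = 0.0,
    style: str = "compositional",
    seed: int | None = None,
) -> GroundTruthCode:
    """Construct the latent code realizing the requested geometry.

    ``alignment`` may be a scalar (uniform off-diagonal cosine) or a full
    positions x positions cosine matrix; it must be a valid Gram target
    (positive semidefinite with unit diagonal).  ``style='conjunctive'``
    replaces the compositional phoneme code with iid per-condition means
    whose positional-additive component has been projected out — the
    non-compositional null.
    """
    n_pos = max(
        [c.length_class for c in cset.conditions if not c.is_rest],
        default=0,
    )
    if n_pos == 0:
        raise ConstructionError("condition set has no sequence conditions")
    m = len(cset.inventory)
    if gains is None:
        gains = default_position_gains(n_pos)
    gains = np.asarray(gains, dtype=float)
    if len(gains) != n_pos or np.any(gains <= 0):
        raise ConstructionError("need one positive gain per position")
    if alignment is None:
        alignment = default_alignment(n_pos)
    elif np.isscalar(alignment):
        alignment = default_alignment(n_pos, float(alignment))
    alignment = np.asarray(alignment, dtype=float)
    if alignment.shape != (n_pos, n_pos):
        raise ConstructionError("alignment matrix shape mismatch")
    if np.any(np.abs(alignment) > 1 + 1e-12):
        raise ConstructionError("alignment entries must lie in [-1, 1]")
    if not np.allclose(alignment, alignment.T):
        raise ConstructionError("alignment matrix must be symmetric")
    evals, evecs = np.linalg.eigh(alignment)
    if np.any(evals < -1e-8):
        raise ConstructionError(
            "alignment matrix is not positive semidefinite"
        )
    if not np.allclose(np.diag(alignment), 1.0):
        raise ConstructionError("alignment diagonal must be 1")
    factor = evecs * np.sqrt(np.clip(evals, 0.0, None))  # rows: positions

    n_lat = config.n_electrodes
    n_private_epochs = len(SIGNAL_EPOCHS) if epoch_private_scale > 0 else 0
    block = m - 1
    need = n_pos * block * (1 + n_private_epochs) + 2
    if need > n_lat:
        raise ConstructionError(
            f"{need} orthogonal latent directions needed but only "
            f"{n_lat} electrodes available; increase n_features"
        )

    rng = np.random.default_rng(
        config.seed if seed is None else seed
    )
    basis, _ = np.linalg.qr(rng.standard_normal((n_lat, need)))
    simplex = _simplex_vertices(m)  # (m, m-1)
    # signal amplitude on the trial-noise scale; unit scale when noiseless
    amp = config.snr * (config.trial_noise_sd or 1.0)

    def position_frames(offset: int) -> list[np.ndarray]:
        blocks = [
            basis[:, offset + k * block: offset + (k + 1) * block]
            for k in range(n_pos)
        ]
        return [
            sum(factor[p, k] * blocks[k] for k in range(n_pos))
            for p in range(n_pos)
        ]

    frames = position_frames(0)
    phoneme_vectors = {
        p + 1: {
            tok: amp * frames[p] @ simplex[j]
            for j, tok in enumerate(cset.inventory)
        }
        for p in range(n_pos)
    }
    cursor = n_pos * block
    length_axis = length_scale * amp * basis[:, cursor]
    boundary_axis = boundary_scale * amp * basis[:, cursor + 1]
    cursor += 2

    epoch_private = None
    if n_private_epochs:
        epoch_private = {}
        for epoch in SIGNAL_EPOCHS:
            eframes = position_frames(cursor)
            cursor += n_pos * block
            epoch_private[epoch] = {
                p + 1: {
                    tok: epoch_private_scale * amp * eframes[p] @ simplex[j]
                    for j, tok in enumerate(cset.inventory)
                }
                for p in range(n_pos)
            }

    conjunctive_means = None
    if style == "conjunctive":
        conjunctive_means = _conjunctive_means(
            rng, cset, n_lat, amp, gains
        )
        # a per-sequence-random code has no systematic length or boundary
        # offsets either — those axes are compositional structure
        length_axis = np.zeros_like(length_axis)
        boundary_axis = np.zeros_like(boundary_axis)
    elif style != "compositional":
        raise ConstructionError(f"unknown code style {style!r}")

    return GroundTruthCode(
        baseline=np.zeros(n_lat),
        phoneme_vectors=phoneme_vectors,
        position_gains=gains,
        alignment=alignment,
        length_axis=length_axis,
        boundary_axis=boundary_axis,
        boundary_gain=float(boundary_gain),
        epoch_gains=dict(epoch_gains or {e: 1.0 for e in SIGNAL_EPOCHS}),
        epoch_private=epoch_private,
        inventory=tuple(cset.inventory),
        conjunctive_means=conjunctive_means,
        meta={"style": style, "amp": amp, "epoch_private_scale":
              epoch_private_scale, "length_scale": length_scale,
              "boundary_scale": boundary_scale},
    )


def _conjunctive_means(rng, cset, n_lat, amp, gains):
    """iid condition means with the positional-additive part projected out.

    Within each (length class, segmentation-arity) family the intercept,
    slot-phoneme one-hot, and two-word-flag columns are regressed out, so
    the surviving code is purely conjunctive (interaction-only).  A single
    common rescale matches the mean signal power of the compositional code.
    """
    conds = [c for c in cset.conditions if not c.is_rest]
    inv = list(cset.inventory)
    by_length: dict[int, list[ConditionLabel]] = {}
    for c in conds:
        by_length.setdefault(c.length_class, []).append(c)
    out: dict[str, np.ndarray] = {}
    for L, group in by_length.items():
        raw = rng.standard_normal((len(group), n_lat))
        cols = [np.ones(len(group))]
        for p in range(L):
            for tok in inv:
                cols.append(
                    np.array([c.consonants[p] == tok for c in group], float)
                )
        if any(c.segmentation for c in group):
            cols.append(np.array([bool(c.segmentation) for c in group], float))
        x = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(x, raw, rcond=None)
        resid = raw - x @ beta
        target = amp * np.sqrt(np.sum(gains[:L] ** 2))
        scale = target / np.sqrt(np.mean(np.sum(resid**2, axis=1)))
        for c, row in zip(group, resid):
            out[c.key] = scale * row
    return out


# ---------------------------------------------------------------------------
# trial plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpochSpec:
    """Trial timing: durations in seconds, uniform jitter where ranged."""

    pre_cue_s: float = 0.4
    cue_s: float = 1.5
    delay_range_s: tuple[float, float] = (1.0, 1.3)
    react_range_s: tuple[float, float] = (0.25, 0.35)
    post_speech_s: float = 1.0

    @property
    def duration_s(self) -> float:
        return (self.pre_cue_s + self.cue_s + self.delay_range_s[1]
                + self.react_range_s[1] + self.post_speech_s)


@dataclass
class TrialPlan:
    labels: tuple[ConditionLabel, ...]
    events: dict[str, np.ndarray]
    block_ids: np.ndarray
    duration_s: float
    condition_set: ConditionSet

    @property
    def n_trials(self) -> int:
        return len(self.labels)


def make_trial_plan(
    cset: ConditionSet,
    repeats: int,
    epoch_spec: EpochSpec | None = None,
    seed: int = 0,
    rest_trials: int = 0,
    block_size: int = 50,
) -> TrialPlan:
    """Balanced, seed-shuffled trial plan with jittered event times."""
    if repeats < 1:
        raise ConstructionError("repeats must be >= 1")
    spec = epoch_spec or EpochSpec()
    rng = np.random.default_rng([seed, 101])
    labels = [c for c in cset.conditions if not c.is_rest] * repeats
    from .task import REST

    labels += [REST] * rest_trials
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    n = len(labels)
    cue_onset = np.full(n, spec.pre_cue_s)
    cue_offset = cue_onset + spec.cue_s
    delay = rng.uniform(*spec.delay_range_s, size=n) \
        if spec.delay_range_s[0] < spec.delay_range_s[1] \
        else np.full(n, spec.delay_range_s[0])
    react = rng.uniform(*spec.react_range_s, size=n) \
        if spec.react_range_s[0] < spec.react_range_s[1] \
        else np.full(n, spec.react_range_s[0])
    go_cue = cue_offset + delay
    speech_onset = go_cue + react
    return TrialPlan(
        labels=tuple(labels),
        events={
            "cue_onset": cue_onset,
            "cue_offset": cue_offset,
            "go_cue": go_cue,
            "speech_onset": speech_onset,
        },
        block_ids=np.arange(n) // block_size,
        duration_s=spec.duration_s,
        condition_set=cset,
    )


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def _bin_epochs(times: np.ndarray, events_row: dict[str, float]) -> np.ndarray:
    """Epoch index per bin: 0 pre, 1 cue, 2 prep, 3 speech (from go cue)."""
    ep = np.zeros(len(times), dtype=int)
    ep[times >= events_row["cue_onset"]] = 1
    ep[times >= events_row["cue_offset"]] = 2
    ep[times >= events_row["go_cue"]] = 3
    return ep


_EPOCH_NAMES = ("pre", "cue", "prep", "speech")


def simulate_session(
    code: GroundTruthCode,
    plan: TrialPlan,
    config: GeneratorConfig,
) -> SessionData:
    """Draw a session from the generative model.

    Per trial and bin the latent electrode activity is the epoch-dependent
    condition mean plus a per-block drift offset, a trial-level noise vector
    shared across bins, and independent per-bin noise in each of the two
    feature streams.  ``poisson-count`` mode instead clips latent rates at
    zero and draws integer counts.
    """
    rng = np.random.default_rng([config.seed, 202])
    n = plan.n_trials
    n_lat = code.n_latent
    times = np.arange(0.0, plan.duration_s - 1e-9, config.bin_s)
    n_bins = len(times)

    known = set(plan.condition_set.keys)
    for lab in plan.labels:
        if not lab.is_rest and lab.key not in known:
            raise LabelError(f"plan condition {lab.key!r} unknown to the set")
        for p in range(1, lab.length_class + 1):
            if (code.conjunctive_means is None
                    and lab.consonant_at(p) not in code.phoneme_vectors[p]):
                raise LabelError(
                    f"consonant {lab.consonant_at(p)!r} not covered by code"
                )

    # epoch means cache: one vector per (condition, epoch)
    mean_cache: dict[tuple[str, str], np.ndarray] = {}

    def get_mean(lab: ConditionLabel, epoch: str) -> np.ndarray:
        key = (lab.key, epoch)
        if key not in mean_cache:
            mean_cache[key] = code.latent_mean(lab, epoch)
        return mean_cache[key]

    n_blocks = int(plan.block_ids.max()) + 1 if n else 0
    drift = rng.standard_normal((n_blocks, n_lat)) * config.drift_sd

    latent = np.empty((n, n_bins, n_lat))
    for i, lab in enumerate(plan.labels):
        ep = _bin_epochs(times, {k: v[i] for k, v in plan.events.items()})
        for e_idx in np.unique(ep):
            latent[i, ep == e_idx] = get_mean(lab, _EPOCH_NAMES[e_idx])
        latent[i] += drift[plan.block_ids[i]]

    latent += (
        rng.standard_normal((n, 1, n_lat)) * config.trial_noise_sd
    )

    if config.noise_model == "gaussian":
        counts = latent + rng.standard_normal(latent.shape) * config.bin_noise_sd
        power = latent + rng.standard_normal(latent.shape) * config.bin_noise_sd
    else:  # poisson-count
        rate = np.clip(config.poisson_base_rate + latent, 0.0, None)
        counts = rng.poisson(rate).astype(float)
        power = rng.poisson(rate).astype(float)

    features = np.concatenate([counts, power], axis=2)
    return SessionData(
        features=features,
        labels=plan.labels,
        events={k: v.copy() for k, v in plan.events.items()},
        block_ids=plan.block_ids.copy(),
        bin_s=config.bin_s,
        condition_set=plan.condition_set,
        meta={
            "generator": {
                "seed": config.seed,
                "snr": config.snr,
                "noise_model": config.noise_model,
                "drift_sd": config.drift_sd,
                "n_features": config.n_features,
                "style": code.meta.get("style", "compositional"),
            }
        },
    )
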