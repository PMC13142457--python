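"""In-memory session container shared by all analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import LabelError, ShapeError
from .task import ConditionLabel, ConditionSet

EVENT_NAMES = ("cue_onset", "cue_offset", "go_cue", "speech_onset")


@dataclass
class SessionData:
    """Binned neural features for one recording session.

    ``features`` is a trials x time-bins x features tensor of 20 ms-binned
    activity (threshold-crossing counts and spike-band power streams
    concatenated along the feature axis).  Per-trial event times are seconds
    from trial start; bin ``i`` covers the half-open interval
    ``[i*bin_s, (i+1)*bin_s)`` on the same clock.
    """

    features: np.ndarray
    labels: tuple[ConditionLabel, ...]
    events: dict[str, np.ndarray]
    block_ids: np.ndarray
    bin_s: float = 0.02
    condition_set: ConditionSet | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = tuple(self.labels)
        self.block_ids = np.asarray(self.block_ids)
        self.events = {k: np.asarray(v, dtype=float)
                       for k, v in self.events.items()}
        self.validate()

    # -- basic introspection --------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    @property
    def n_bins(self) -> int:
        return self.features.shape[1]

    @property
    def n_features(self) -> int:
        return self.features.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Bin start times in seconds from trial start."""
        return np.arange(self.n_bins) * self.bin_s

    @property
    def label_keys(self) -> np.ndarray:
        return np.array([lab.key for lab in self.labels])

    def validate(self) -> None:
        if self.features.ndim != 3:
            raise ShapeError("features must be trials x bins x features")
        n = self.features.shape[0]
        if len(self.labels) != n or len(self.block_ids) != n:
            raise ShapeError("labels/block_ids length mismatch with trials")
        for name in EVENT_NAMES:
            if name not in self.events:
                raise LabelError(f"missing event column {name!r}")
            if len(self.events[name]) != n:
                raise ShapeError(f"event {name!r} length mismatch")
        ev = np.stack([self.events[name] for name in EVENT_NAMES], axis=1)
        finite = np.all(np.isfinite(ev), axis=1)
        if np.any(np.diff(ev[finite], axis=1) <= 0):
            raise LabelError("event times must strictly increase per trial")
        if self.condition_set is not None:
            known = set(self.condition_set.keys)
            for lab in self.labels:
                if lab.key not in known:
                    raise LabelError(
                        f"trial label {lab.key!r} not in the condition set"
                    )

    # -- selection helpers ----------------------------------------------
    def trial_indices(self, keys) -> np.ndarray:
        keys = set(keys)
        return np.array(
            [i for i, lab in enumerate(self.labels) if lab.key in keys],
            dtype=int,
        )

    def subset(self, idx) -> "SessionData":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            features=self.features[idx],
            labels=tuple(self.labels[i] for i in idx),
            events={k: v[idx] for k, v in self.events.items()},
            block_ids=self.block_ids[idx],
        )

    def with_labels(self, labels) -> "SessionData":
        return replace(self, labels=tuple(labels))


def shuffle_labels(session: SessionData, seed: int = 0) -> SessionData:
    """Permute trial labels — the leakage sentinel used throughout tests."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(session.n_trials)
    return session.with_labels([session.labels[i] for i in perm])
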