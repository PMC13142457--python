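"""On-disk session bundles.

A bundle is a directory with human-readable JSON metadata, a dense ``.npy``
feature tensor, and a CSV trial table — deliberately simple so converters
to richer neurophysiology containers are easy to write.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SessionIOError
from .session import EVENT_NAMES, SessionData
from .task import ConditionLabel, ConditionSet

SCHEMA_VERSION = 1

METADATA_FILE = "metadata.json"
FEATURES_FILE = "features.npy"
TRIALS_FILE = "trials.csv"


def write_session(session: SessionData, path) -> Path:
    """Write a session bundle; round-trip stable (bit-identical features)."""
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "schema_version": SCHEMA_VERSION,
            "bin_s": session.bin_s,
            "n_trials": session.n_trials,
            "n_bins": session.n_bins,
            "n_features": session.n_features,
            "events": list(EVENT_NAMES),
            "condition_set": (
                json.loads(session.condition_set.to_json())
                if session.condition_set is not None else None
            ),
            "provenance": session.meta,
        }
        (path / METADATA_FILE).write_text(json.dumps(meta, indent=1))
        np.save(path / FEATURES_FILE, session.features)
        table = {
            "label_key": [lab.key for lab in session.labels],
            "consonants": ["-".join(lab.consonants)
                           for lab in session.labels],
            "segmentation": ["-".join(map(str, lab.segmentation))
                             for lab in session.labels],
            "template": [lab.template for lab in session.labels],
            "block_id": session.block_ids,
        }
        for name in EVENT_NAMES:
            table[name] = session.events[name]
        pd.DataFrame(table).to_csv(path / TRIALS_FILE, index=False)
    except OSError as exc:
        raise SessionIOError(f"cannot write bundle at {path}: {exc}") from exc
    return path


def read_session(path) -> SessionData:
    """Load and validate a session bundle written by :func:`write_session`."""
    path = Path(path)
    meta_path = path / METADATA_FILE
    if not meta_path.exists():
        raise SessionIOError(f"no session bundle at {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SessionIOError(f"corrupt metadata in {path}: {exc}") from exc
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SessionIOError(
            f"schema version mismatch: bundle has {version!r}, "
            f"reader supports {SCHEMA_VERSION}"
        )
    try:
        features = np.load(path / FEATURES_FILE)
    except (OSError, ValueError, EOFError) as exc:
        raise SessionIOError(
            f"corrupt or truncated feature tensor in {path}: {exc}"
        ) from exc
    try:
        trials = pd.read_csv(path / TRIALS_FILE, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise SessionIOError(f"corrupt trial table in {path}: {exc}") from exc
    for name in EVENT_NAMES:
        if name not in trials.columns:
            raise SessionIOError(f"trial table missing event column {name!r}")
    if features.shape[0] != len(trials) \
            or features.shape != (meta["n_trials"], meta["n_bins"],
                                  meta["n_features"]):
        raise SessionIOError("feature tensor shape disagrees with metadata")
    cset = None
    if meta.get("condition_set") is not None:
        cset = ConditionSet.from_json(json.dumps(meta["condition_set"]))
    vowel = cset.vowel if cset is not None else "AH"
    labels = []
    for _, row in trials.iterrows():
        cons = tuple(str(row["consonants"]).split("-")) \
            if row["consonants"] else ()
        seg = tuple(int(x) for x in str(row["segmentation"]).split("-")
                    if x != "")
        labels.append(ConditionLabel(
            consonants=cons, vowel=vowel, segmentation=seg,
            template=row["template"],
        ))
    return SessionData(
        features=features,
        labels=tuple(labels),
        events={name: trials[name].to_numpy(dtype=float)
                for name in EVENT_NAMES},
        block_ids=trials["block_id"].to_numpy(dtype=int),
        bin_s=float(meta["bin_s"]),
        condition_set=cset,
        meta=meta.get("provenance", {}),
    )
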