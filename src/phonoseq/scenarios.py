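"""Config-driven scenario runner.

Each scenario reproduces one figure-level analysis chain end-to-end on a
synthetic or loaded session: generate/load -> preprocess -> analyze ->
summarize.  Results are plain dicts (JSON-serializable) with every seed,
window, and test family recorded, so identical configs yield identical
summaries.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .analyses import (
    cross_epoch_generalization,
    cross_position_generalization,
    pairwise_position_decoding,
    sequence_length_decoding,
    word_boundary_analysis,
)
from .encoding import build_design_matrix, coefficient_similarity, \
    fit_and_validate
from .exceptions import ConfigError
from .geometry import GroupSpec, compositional_predict, displacement_vectors, \
    marginal_means, plane_variance_2d
from .io import read_session
from .lda import fit_diag_lda, project
from .preprocess import PREP_05, PREP_06, PREP_07, PREP_08, extract_windows, \
    zscore_session
from .session import SessionData, shuffle_labels
from .stats import bh_fdr
from .synth import (
    GeneratorConfig,
    make_ground_truth_code,
    make_trial_plan,
    simulate_session,
)
from .task import (
    build_full_factorial,
    build_length_series,
    build_word_boundary_set,
)

SCENARIOS = (
    "fig1_pairwise",
    "fig2_geometry_encoding",
    "fig3_length",
    "fig4_generalization",
    "fig5_words_boundary",
    "recovery_suite",
)


# ---------------------------------------------------------------------------
# session sources
# ---------------------------------------------------------------------------

def build_condition_set(spec: dict):
    design = spec.get("design", "factorial")
    inventory = tuple(spec.get("inventory", ("K", "N", "SH")))
    if design == "factorial":
        return build_full_factorial(inventory, int(spec.get("n_slots", 3)))
    if design == "lengths":
        return build_length_series(inventory, spec.get("lengths", (1, 2, 3)))
    if design == "boundary":
        return build_word_boundary_set(
            inventory, int(spec.get("n_slots", 4)),
            int(spec.get("boundary_slot", 2)),
        )
    if design == "words":
        return build_full_factorial(
            inventory, int(spec.get("n_slots", 3)), template="WWW"
        )
    raise ConfigError(f"unknown design {design!r}")


def generate_session(spec: dict, seed: int):
    """Generate a z-scored session plus its ground-truth code from a spec."""
    cset = build_condition_set(spec)
    config = GeneratorConfig(
        n_features=int(spec.get("n_features", 128)),
        snr=float(spec.get("snr", 2.0)),
        noise_model=spec.get("noise_model", "gaussian"),
        drift_sd=float(spec.get("drift_sd", 0.2)),
        trial_noise_sd=float(spec.get("trial_noise_sd", 1.0)),
        bin_noise_sd=float(spec.get("bin_noise_sd", 1.0)),
        seed=seed,
    )
    code = make_ground_truth_code(
        config, cset,
        alignment=spec.get("alignment"),
        gains=spec.get("gains"),
        length_scale=float(spec.get("length_scale", 1.0)),
        boundary_scale=float(spec.get("boundary_scale", 1.5)),
        boundary_gain=float(spec.get("boundary_gain", 1.0)),
        epoch_gains=spec.get("epoch_gains"),
        epoch_private_scale=float(spec.get("epoch_private_scale", 0.0)),
        style=spec.get("style", "compositional"),
    )
    plan = make_trial_plan(
        cset, repeats=int(spec.get("repeats", 15)), seed=seed,
        rest_trials=int(spec.get("rest_trials", 0)),
    )
    session = simulate_session(code, plan, config)
    block_subtract = bool(spec.get("block_subtract", True))
    return zscore_session(session, block_subtract=block_subtract), code


def resolve_session(config: dict) -> tuple[SessionData, object | None]:
    if "bundle" in config:
        session = read_session(config["bundle"])
        return zscore_session(session), None
    session, code = generate_session(
        config.get("generator", {}), int(config.get("seed", 0))
    )
    if config.get("shuffle_labels"):
        session = shuffle_labels(session, seed=int(config.get("seed", 0)))
    return session, code


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _fig1(session: SessionData, cfg: dict) -> dict:
    seed = int(cfg.get("seed", 0))
    n_boot = int(cfg.get("n_boot", 1000))
    positions = cfg.get("positions")
    if positions is None:
        positions = list(range(1, max(
            lab.length_class for lab in session.labels if not lab.is_rest
        ) + 1))
    out = {"window": "go_cue[-0.8,0)", "positions": {}}
    pvals = []
    for p in positions:
        res = pairwise_position_decoding(
            session, p, window=PREP_08, n_boot=n_boot, seed=seed
        )
        out["positions"][str(p)] = {
            "mean_auc": res.mean_auc,
            "ci": list(res.ci),
            "p": res.p_value,
            "n_pairs": res.n_pairs,
        }
        pvals.append(res.p_value)
    rejected, adjusted = bh_fdr(np.array(pvals))
    for i, p in enumerate(positions):
        out["positions"][str(p)]["p_fdr"] = float(adjusted[i]) \
            if np.isfinite(adjusted[i]) else None
        out["positions"][str(p)]["significant"] = bool(rejected[i])
    out["fdr_family"] = "positions within this array"
    return out


def _fig2(session: SessionData, cfg: dict) -> dict:
    seed = int(cfg.get("seed", 0))
    n_boot = int(cfg.get("n_boot", 1000))
    n_perm = int(cfg.get("n_perm", 500))
    rng = np.random.default_rng(seed)
    out = {"window": "go_cue[-0.7,0)"}

    gen = {}
    for a, b in ((2, 3), (3, 2), (1, 2)):
        r = cross_position_generalization(
            session, a, b, window=PREP_07, seed=seed, n_boot=n_boot
        )
        gen[f"{a}to{b}"] = {
            "auc_within": r.auc_within, "auc_cross": r.auc_cross,
            "normalized_generalization": r.normalized_generalization,
            "ci": list(r.ci) if r.ci else None,
        }
    out["cross_position"] = gen

    # geometry in the discriminant space of a 3rd-position decoder
    ext = extract_windows(session, PREP_07, mode="average")
    labs = [session.labels[i] for i in ext.kept]
    full = [i for i, lab in enumerate(labs) if lab.length_class >= 3]
    y3 = np.array([labs[i].consonant_at(3) for i in full])
    x = ext.matrix[full]
    train = rng.random(len(full)) < float(cfg.get("train_frac", 0.5))
    if train.sum() < 3 or (~train).sum() < 3:
        raise ConfigError("too few trials for the geometry split")
    model = fit_diag_lda(x[train], y3[train])
    z = project(model, x[~train])
    held_labs = [labs[full[i]] for i in np.flatnonzero(~train)]
    base = marginal_means(z, held_labs, GroupSpec(slots=(3,)))
    refined = marginal_means(z, held_labs, GroupSpec(slots=(2, 3)))
    disp = displacement_vectors(base, refined)
    out["n_displacement_vectors"] = len(disp.vectors)
    # plane fit in full feature space: 9 means marginalizing 1st position
    full_labs = [labs[i] for i in full]
    mm9 = marginal_means(x, full_labs, GroupSpec(slots=(2, 3)))
    out["plane_variance_2d_pos23_means"] = plane_variance_2d(
        np.array(list(mm9.means.values()))
    )

    # encoding model on the full feature space
    design = build_design_matrix(
        labs, session.condition_set.inventory,
        max(lab.length_class for lab in labs),
    )
    _, rep = fit_and_validate(
        design, ext.matrix, alpha=0.5, seed=seed,
        n_boot=n_boot, n_perm=n_perm,
    )
    _, cos = coefficient_similarity(
        design, ext.matrix, alpha=0.5, n_perm=n_perm, n_boot=n_boot,
        seed=seed,
    )
    out["encoding"] = {
        "r2_condition": rep.r2_condition,
        "r2_single_trial": rep.r2_single_trial,
        "p_condition": rep.p_condition,
        "cosine_summaries": {
            f"{a}to{b}": v for (a, b), v in
            cos.position_pair_summary.items()
        },
        "cosine_p": {
            f"{a}to{b}": v for (a, b), v in
            (cos.position_pair_p or {}).items()
        },
    }
    return out


def _fig3(session: SessionData, cfg: dict) -> dict:
    seed = int(cfg.get("seed", 0))
    n_perm = int(cfg.get("n_perm", 500))
    n_boot = int(cfg.get("n_boot", 1000))
    rng = np.random.default_rng(seed)
    res = sequence_length_decoding(
        session, window=PREP_06, n_perm=n_perm, seed=seed, n_boot=n_boot
    )
    out = {
        "window": "go_cue[-0.6,0)",
        "length_decoding": {
            "normalized_balanced_accuracy":
                res.normalized_balanced_accuracy,
            "p": res.p_value,
            "ci": list(res.ci) if res.ci else None,
            "chance": res.chance,
        },
    }
    # joint (length, first consonant) LDA, geometry on held-out projections
    ext = extract_windows(session, PREP_06, mode="average")
    labs = [session.labels[i] for i in ext.kept]
    joint = np.array([
        f"L{lab.length_class}-{lab.consonant_at(1)}" for lab in labs
    ])
    train = rng.random(len(labs)) < float(cfg.get("train_frac", 0.6))
    model = fit_diag_lda(ext.matrix[train], joint[train])
    z = project(model, ext.matrix[~train])
    held = [labs[i] for i in np.flatnonzero(~train)]
    comp = compositional_predict(
        z, held, n_boot=n_boot, n_perm=n_perm, seed=seed
    )
    out["joint_classes"] = int(len(np.unique(joint)))
    out["compositional"] = {
        "r2_condition": comp.r2_condition,
        "r2_single_trial": comp.r2_single_trial,
        "p_condition": comp.p_condition,
        "p_single_trial": comp.p_single_trial,
    }
    return out


def _fig4(session: SessionData, cfg: dict) -> dict:
    positions = cfg.get("positions", [1, 2, 3])
    out = {"positions": {}}
    for p in positions:
        r = cross_epoch_generalization(session, p)
        out["positions"][str(p)] = {
            "auc": r.auc, "peak_times": r.peak_times,
        }
    aucs = [out["positions"][str(p)]["auc"] for p in positions]
    out["mean_auc"] = {
        k: float(np.mean([a[k] for a in aucs]))
        for k in ("cue", "prep", "speech")
    }
    return out


def _fig5(session: SessionData, cfg: dict) -> dict:
    seed = int(cfg.get("seed", 0))
    # real-word sequence decoding: a separate session of word triplets with
    # a short, first-word-dominant planning horizon
    words_spec = {
        "design": "words",
        "inventory": ("clouds", "vanish", "abruptly"),
        "gains": [1.0, 0.4, 0.15],
        "repeats": int(cfg.get("generator", {}).get("word_repeats", 15)),
    }
    words_spec.update(cfg.get("words_generator", {}))
    word_session, _ = generate_session(words_spec, seed)
    word_positions = {}
    pvals = []
    for p in (1, 2, 3):
        r = pairwise_position_decoding(
            word_session, p, window=PREP_05,
            n_boot=int(cfg.get("n_boot", 1000)), seed=seed,
        )
        word_positions[str(p)] = {"mean_auc": r.mean_auc,
                                  "ci": list(r.ci), "p": r.p_value}
        pvals.append(r.p_value)
    rejected, adjusted = bh_fdr(np.array(pvals))
    for i, p in enumerate(("1", "2", "3")):
        word_positions[p]["significant"] = bool(rejected[i])

    res = word_boundary_analysis(session, window=PREP_05, seed=seed)
    return {
        "real_words": {"positions": word_positions,
                       "n_conditions": len(word_session.condition_set)},
        "window": "go_cue[-0.5,0)",
        "boundary": {
            "auc": res.boundary_auc,
            "ci": list(res.boundary_ci),
            "p": res.boundary_p,
        },
        "late_positions": {
            "one_word_auc": res.one_word_auc,
            "two_word_auc": res.two_word_auc,
            "delta_auc": res.delta_auc,
            "delta_p": res.delta_p,
            "one_word_p": res.one_word_p,
            "two_word_p": res.two_word_p,
            "n_pairs": int(len(res.one_word_pair_aucs)),
        },
    }


def _recovery(config: dict) -> dict:
    """Alignment parameter recovery over a grid of target cosines."""
    seed = int(config.get("seed", 0))
    gen = dict(config.get("generator", {}))
    grid = config.get("c_grid", (0.0, 0.3, 0.6, 0.9))
    rows = []
    for i, c in enumerate(grid):
        spec = dict(gen, alignment=float(c))
        spec.setdefault("repeats", 30)
        spec.setdefault("gains", [1.0, 1.0, 1.0])
        session, _ = generate_session(spec, seed + i)
        ext = extract_windows(session, PREP_07, mode="average")
        labs = [session.labels[j] for j in ext.kept]
        design = build_design_matrix(
            labs, session.condition_set.inventory,
            max(lab.length_class for lab in labs),
        )
        _, cos = coefficient_similarity(
            design, ext.matrix, alpha=0.5, n_perm=0, n_boot=0, seed=seed
        )
        gen23 = cross_position_generalization(
            session, 2, 3, window=PREP_07, seed=seed, n_boot=0
        )
        rows.append({
            "c_target": float(c),
            "cosine_2to3": cos.position_pair_summary[(2, 3)],
            "cosine_1to2": cos.position_pair_summary[(1, 2)],
            "normalized_generalization_2to3":
                gen23.normalized_generalization,
        })
    return {"grid": rows}


def run_scenario(config: dict) -> dict:
    """Run one named scenario and return its machine-readable summary."""
    name = config.get("scenario")
    if name not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {name!r}; valid: {', '.join(SCENARIOS)}"
        )
    config = dict(config)
    gen = dict(SCENARIO_GENERATORS.get(name, {}))
    gen.update(config.get("generator", {}))
    if gen:
        config["generator"] = gen
    out = {
        "scenario": name,
        "seed": int(config.get("seed", 0)),
        "config": {k: v for k, v in config.items() if k != "scenario"},
    }
    if name == "recovery_suite":
        out["results"] = _recovery(config)
        return out
    session, _ = resolve_session(config)
    runner = {
        "fig1_pairwise": _fig1,
        "fig2_geometry_encoding": _fig2,
        "fig3_length": _fig3,
        "fig4_generalization": _fig4,
        "fig5_words_boundary": _fig5,
    }[name]
    out["results"] = runner(session, config)
    return out


#: generator specs matching each scenario's task design
SCENARIO_GENERATORS = {
    "fig1_pairwise": {"design": "factorial", "n_slots": 3},
    "fig2_geometry_encoding": {"design": "factorial", "n_slots": 3},
    "fig3_length": {"design": "lengths", "lengths": (1, 2, 3)},
    "fig4_generalization": {"design": "factorial", "n_slots": 3,
                            "repeats": 20},
    "fig5_words_boundary": {"design": "boundary", "n_slots": 4,
                            "boundary_slot": 2, "repeats": 12},
}


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _walk(prefix, obj, lines):
    if isinstance(obj, dict):
        for k, v in obj.items():
            _walk(f"{prefix}.{k}" if prefix else str(k), v, lines)
    elif isinstance(obj, (list, tuple)) and obj and \
            isinstance(obj[0], (dict, list)):
        for i, v in enumerate(obj):
            _walk(f"{prefix}[{i}]", v, lines)
    else:
        if isinstance(obj, float):
            obj = f"{obj:.4g}"
        lines.append(f"{prefix:58s} {obj}")


def report(results: dict, path=None) -> str:
    """Render a results bundle as an aligned, human-readable table."""
    lines = [f"phonoseq scenario report: {results.get('scenario', '?')}",
             "=" * 72]
    _walk("", results.get("results", {}), lines)
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_results(results: dict, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "summary.json").write_text(
        json.dumps(_jsonable(results), indent=1)
    )
    report(_jsonable(results), out_dir / "report.txt")
    return out_dir
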