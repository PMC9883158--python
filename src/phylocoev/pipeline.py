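"""End-to-end orchestration: signal -> coevolution -> sequential evolution.

``run_pipeline`` runs the enabled stages on a tree sample plus society
table (or on a freshly simulated dataset), writes each stage's CSV outputs
and a manifest JSON recording input hashes, seeds and configuration, and
keeps stages independent: a failing stage is recorded and does not abort
the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import coevolution as coev
from . import multistate as ms
from . import signal as sig
from .simulate import SyntheticConfig, make_dataset, write_dataset
from .trees import TreeSample, parse_trees

log = logging.getLogger("phylocoev")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_NOT_CONVERGED = 3

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_inputs"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``scale`` switches between desk-scale defaults and full production run
    sizes (100 tree draws, long multistate chains).
    """

    out_dir: str = "phylocoev_out"
    trees_path: str | None = None
    data_path: str | None = None
    simulate: bool = False
    n_tips: int = 60
    seed: int = 0
    scale: str = "desk"  # or "paper"
    tree_draws: int | None = None
    stages: tuple = ("signal", "coevolve", "multistate", "compare")
    models: tuple = (
        "full",
        "weak_differentiation",
        "strong_differentiation",
        "weak_unification",
        "strong_unification",
    )
    require_convergence: bool = False

    def __post_init__(self) -> None:
        if self.scale not in ("desk", "paper"):
            raise ValueError("scale must be 'desk' or 'paper'")
        if not self.simulate and (self.trees_path is None or self.data_path is None):
            raise ValueError("either simulate=True or provide trees_path and data_path")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_inputs(config: RunConfig):
    """(TreeSample, society table, coords) from files or the simulator."""
    if config.simulate:
        ds = make_dataset(SyntheticConfig(n_tips=config.n_tips, seed=config.seed))
        trees = TreeSample([ds.tree])
        table = ds.society_table
    else:
        tp = Path(config.trees_path)
        fmt = "nexus" if tp.suffix.lower() in (".nex", ".nexus", ".trees") else "newick"
        trees = parse_trees(tp.read_text(), fmt)
        table = pd.read_csv(config.data_path)
    coords = table[["lat", "lon"]].to_numpy(dtype=float) if {"lat", "lon"} <= set(table.columns) else None
    return trees, table, coords


def validate_inputs(trees: TreeSample, table: pd.DataFrame) -> dict:
    """Cross-check the tree sample against the society table.

    Reports (without raising): taxa present in trees but absent from the
    table, table rows without a matching tip, societies mapped to more than
    one taxon, and ordinal values outside 0..3.
    """
    report = {
        "taxa_not_in_table": [],
        "rows_not_in_trees": [],
        "duplicate_society_taxa": [],
        "out_of_range_values": [],
    }
    tips = set(trees[0].tip_labels)
    tab_taxa = set(table["taxon"].astype(str))
    report["taxa_not_in_table"] = sorted(tips - tab_taxa)
    report["rows_not_in_trees"] = sorted(tab_taxa - tips)
    if "society" in table.columns:
        counts = table.groupby("society")["taxon"].nunique()
        report["duplicate_society_taxa"] = sorted(counts[counts > 1].index.tolist())
    for col in ("political_authority", "religious_authority", "authority_structure"):
        if col in table.columns:
            vals = pd.to_numeric(table[col], errors="coerce")
            bad = table.loc[vals.isna() | (vals < 0) | (vals > 3), "taxon"].tolist()
            if bad:
                report["out_of_range_values"].append({col: sorted(map(str, bad))})
    report["ok"] = not (
        report["taxa_not_in_table"]
        or report["rows_not_in_trees"]
        or report["duplicate_society_taxa"]
        or report["out_of_range_values"]
    )
    return report


def _stage_signal(trees, table, coords, config: RunConfig, out: Path) -> dict:
    draws = config.tree_draws or (100 if config.scale == "paper" else 5)
    cfg = sig.SignalConfig(seed=config.seed, tree_draws=draws)
    post = sig.fit_signal_model(table, trees, cfg)
    path = out / "signal_summary.csv"
    post.summary().to_csv(path, index=False)
    return {"outputs": [path.name], "converged": post.converged}


def _stage_coevolve(trees, table, coords, config: RunConfig, out: Path) -> dict:
    draws = config.tree_draws or (100 if config.scale == "paper" else 3)
    cfg = coev.CoevConfig(seed=config.seed, tree_draws=draws, gp=coords is not None)
    post = coev.fit_coevolution(table, trees, coords, cfg)
    files = []
    p = out / "coevolution_summary.csv"
    post.summary().to_csv(p, index=False)
    files.append(p.name)
    dt = coev.delta_theta(post)
    p = out / "delta_theta.csv"
    pd.DataFrame(
        [
            {"direction": k, "median": v["median"], "hpdi_low": v["hpdi"][0],
             "hpdi_high": v["hpdi"][1], "pp": v.get("pp"), "logbf": v.get("logbf")}
            for k, v in dt.items()
        ]
    ).to_csv(p, index=False)
    files.append(p.name)
    med = coev.OUParams(
        A=np.array(
            [
                [np.median(post.pooled("A11")), np.median(post.pooled("A12"))],
                [np.median(post.pooled("A21")), np.median(post.pooled("A22"))],
            ]
        ),
        b=np.array([np.median(post.pooled("b1")), np.median(post.pooled("b2"))]),
        cutpoints=np.array(
            [
                [np.median(post.pooled("cut_pol_1")), 0.0, np.median(post.pooled("cut_pol_3"))],
                [np.median(post.pooled("cut_rel_1")), 0.0, np.median(post.pooled("cut_rel_3"))],
            ]
        ),
    )
    p = out / "phase_plane.csv"
    coev.phase_plane(med).to_frame().to_csv(p, index=False)
    files.append(p.name)
    p = out / "ancestral_states.csv"
    coev.ancestral_states(post).to_csv(p, index=False)
    files.append(p.name)
    return {"outputs": files, "converged": post.converged}


def _stage_multistate(trees, table, coords, config: RunConfig, out: Path) -> dict:
    states = dict(zip(table["taxon"].astype(str), table["authority_structure"].astype(int)))
    if config.scale == "paper":
        cfg = ms.MultistateConfig.paper_scale(seed=config.seed)
    else:
        cfg = ms.MultistateConfig(seed=config.seed)
    logml = {}
    for name in config.models:
        model = ms.build_rate_model(name)
        logml[name] = ms.stepping_stone_logml(trees, states, model, cfg)
        log.info("stage=multistate model=%s logML=%.3f", name, logml[name])
    p = out / "logml.csv"
    pd.DataFrame({"model": list(logml), "log_marginal_likelihood": list(logml.values())}).to_csv(
        p, index=False
    )
    return {"outputs": [p.name], "logml": logml, "converged": True}


def _stage_compare(trees, table, coords, config: RunConfig, out: Path, logml: dict) -> dict:
    comp = ms.compare_models(logml)
    p = out / "bf_matrix.csv"
    pd.DataFrame(comp.bf2ln, index=comp.names, columns=comp.names).to_csv(p)
    p2 = out / "bf_labels.csv"
    pd.DataFrame(comp.labels, index=comp.names, columns=comp.names).to_csv(p2)
    return {"outputs": [p.name, p2.name], "best": comp.best(), "converged": True}


def run_pipeline(config: RunConfig) -> tuple[int, dict]:
    """Run the enabled stages; returns (exit code, manifest).

    Exit codes: 0 success, 2 input validation failure, 3 required stage not
    converged.  Stage failures are recorded in the manifest; a failed stage
    does not abort independent stages (``compare`` depends on
    ``multistate``).
    """
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO, format="%(asctime)s %(name)s %(message)s"
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trees, table, coords = load_inputs(config)
    if config.simulate:
        write_dataset(
            make_dataset(SyntheticConfig(n_tips=config.n_tips, seed=config.seed)), out / "synthetic"
        )
    report = validate_inputs(trees, table)
    manifest: dict = {
        "seed": config.seed,
        "scale": config.scale,
        "validation": report,
        "stages": {},
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in config.__dict__.items()},
    }
    if not report["ok"]:
        log.error("input validation failed: %s", report)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        return EXIT_VALIDATION, manifest
    if not config.simulate:
        manifest["input_hashes"] = {
            "trees": _sha256(Path(config.trees_path)),
            "data": _sha256(Path(config.data_path)),
        }
    logml = None
    exit_code = EXIT_OK
    for stage in config.stages:
        t0 = time.time()
        log.info("stage=%s start", stage)
        try:
            if stage == "signal":
                res = _stage_signal(trees, table, coords, config, out)
            elif stage == "coevolve":
                res = _stage_coevolve(trees, table, coords, config, out)
            elif stage == "multistate":
                res = _stage_multistate(trees, table, coords, config, out)
                logml = res["logml"]
            elif stage == "compare":
                if logml is None:
                    raise RuntimeError("compare requires the multistate stage")
                res = _stage_compare(trees, table, coords, config, out, logml)
            else:
                raise ValueError(f"unknown stage {stage!r}")
            res["seconds"] = round(time.time() - t0, 2)
            manifest["stages"][stage] = res
            if config.require_convergence and not res.get("converged", True):
                exit_code = EXIT_NOT_CONVERGED
            log.info("stage=%s done in %.1fs", stage, res["seconds"])
        except Exception as e:  # noqa: BLE001 - stage isolation is intentional
            log.exception("stage=%s failed", stage)
            manifest["stages"][stage] = {"error": f"{type(e).__name__}: {e}"}
            if stage in config.stages:
                exit_code = exit_code or EXIT_NOT_CONVERGED
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return exit_code, manifest
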