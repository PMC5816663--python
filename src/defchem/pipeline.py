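"""End-to-end analysis: records -> coding -> model fits -> LRT -> ASR -> complexity.

``run_full_analysis`` consumes a YAML config naming a chronogram, an
occurrence table and (optionally) a pathway, runs the full comparative
analysis, and writes every artifact plus a reproducibility manifest into
an output directory.  Paths in the config are resolved relative to the
config file.  Model selection follows sequential likelihood-ratio tests
from the simplest model toward the most general along valid nesting chains
at alpha = 0.05; AIC is reported alongside, and decides between non-nested
alternatives (e.g. the custom stage matrix vs SYM).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

import defchem
from defchem import bm, calibration, coding, mk, simulate, tree as treemod
from defchem.errors import DefchemError, ValidationError
from defchem.pathway import load_default_pathway, load_pathway

log = logging.getLogger("defchem")

__all__ = ["run_full_analysis", "build_models", "select_best_model"]

DEFAULT_CONFIG = {
    "seed": 0,
    "root": "fitzjohn",
    "threshold": 0.75,
    "alpha": 0.05,
    "n_restarts": 5,
    "stage_models": ["ER", "SYM", "ARD", "stage"],
    "class_models": ["ER"],
    "class_policy": "polymorphic",
    "out_dir": "defchem_out",
}


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_models(name: str, states: mk.StateSpace) -> mk.RateModel:
    """Resolve a model name (ER/SYM/ARD/stage or an index-matrix file path)."""
    key = name.upper()
    if key == "ER":
        return mk.RateModel.er(states)
    if key == "SYM":
        return mk.RateModel.sym(states)
    if key == "ARD":
        return mk.RateModel.ard(states)
    if name.lower() == "stage":
        model = mk.build_stage_model()
        if tuple(states.labels) != tuple(model.states.labels):
            raise ValidationError("the stage model applies to the 3-state stage character")
        return model
    if os.path.exists(name):
        return mk.read_index_matrix(name, states)
    raise ValidationError(f"unknown model {name!r}")


def _is_nested(a: mk.RateModel, b: mk.RateModel) -> bool:
    """True when every constraint of ``b`` is loosenable from ``a``:
    a's structural zeros include b's... i.e. a is nested in b."""
    Ma, Mb = a.index_matrix, b.index_matrix
    # a nested in b: wherever a allows a transition b must allow it, and
    # b's parameter classes refine a's (each a-class maps into b-classes
    # without forcing b to merge distinct a-classes is automatic; the
    # standard families used here satisfy it when classes of b refine a).
    if ((Ma > 0) & (Mb == 0)).any():
        return False
    if a.n_params >= b.n_params:
        return False
    # each of b's classes must lie inside one a-class (b refines a) over
    # transitions a allows
    mask = Ma > 0
    for pid in set(Mb[mask]):
        if pid == 0:
            continue
        sel = mask & (Mb == pid)
        if sel.any() and len(set(Ma[sel])) > 1:
            return False
    return True


def select_best_model(
    fits: dict[str, mk.FitResult], alpha: float = 0.05
) -> tuple[str, pd.DataFrame]:
    """Sequential LRT from simplest to most general; AIC breaks non-nested ties.

    Returns the chosen model name and a table of all pairwise LRTs
    performed (nested pairs only).
    """
    order = sorted(fits, key=lambda n: (fits[n].n_params, n))
    rows = []
    current = order[0]
    for name in order[1:]:
        if _is_nested(fits[current].model, fits[name].model):
            res = mk.likelihood_ratio_test(fits[current], fits[name])
            rows.append(
                {
                    "nested": current,
                    "general": name,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "rejected_at_alpha": res.p_value < alpha,
                }
            )
            if res.p_value < alpha:
                current = name
        else:
            # non-nested: prefer the lower AIC
            better = name if fits[name].aic < fits[current].aic else current
            rows.append(
                {
                    "nested": current,
                    "general": name,
                    "statistic": np.nan,
                    "df": 0,
                    "p_value": np.nan,
                    "rejected_at_alpha": better == name,
                }
            )
            current = better
    return current, pd.DataFrame(rows)


@dataclass
class RunManifest:
    inputs: dict
    seed: int
    version: str
    parameters: dict
    outputs: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "inputs": self.inputs,
                "seed": self.seed,
                "version": self.version,
                "parameters": self.parameters,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def _fit_character(
    tree, data, states, model_names, root, n_restarts, seed, alpha, label, outdir, outputs
):
    fits = {}
    models = {name: build_models(name, states) for name in model_names}
    for name in sorted(models, key=lambda n: (models[n].n_params, n)):
        model = models[name]
        # warm-start from already-fitted nested models so nested logL
        # orderings survive optimization noise
        warm = [
            mk.nested_warm_start(fits[prev], model)
            for prev in fits
            if _is_nested(fits[prev].model, model)
        ]
        fit = mk.fit_mk(
            tree, data, model, root, n_restarts=n_restarts, seed=seed, extra_starts=warm
        )
        fits[name] = fit
        log.info(
            "%s character, model %s: logL=%.6f params=%d converged=%s",
            label, name, fit.log_likelihood, fit.n_params, fit.converged,
        )
    fit_table = pd.DataFrame(
        {
            "model": list(fits),
            "log_likelihood": [fits[m].log_likelihood for m in fits],
            "n_params": [fits[m].n_params for m in fits],
            "AIC": [fits[m].aic for m in fits],
            "converged": [fits[m].converged for m in fits],
        }
    )
    path = os.path.join(outdir, f"{label}_model_fits.tsv")
    fit_table.to_csv(path, sep="\t", index=False)
    outputs[os.path.basename(path)] = path
    if len(fits) > 1:
        best, lrt_table = select_best_model(fits, alpha)
        lpath = os.path.join(outdir, f"{label}_lrt.tsv")
        lrt_table.to_csv(lpath, sep="\t", index=False)
        outputs[os.path.basename(lpath)] = lpath
    else:
        best = next(iter(fits))
    log.info("%s character: best model by sequential LRT is %s", label, best)
    return fits, best


def run_full_analysis(config_path: str) -> str:
    """Run the complete comparative analysis described by a YAML config.

    Returns the output directory.  Any stage failure aborts with the stage
    name; outputs written before the failure are marked partial in the
    manifest location by the absence of ``manifest.json``.
    """
    with open(config_path) as fh:
        user_cfg = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **user_cfg}
    base = os.path.dirname(os.path.abspath(config_path))

    def resolve(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    outdir = resolve(cfg["out_dir"])
    os.makedirs(outdir, exist_ok=True)
    seed = int(cfg["seed"])
    root = cfg["root"]
    alpha = float(cfg["alpha"])
    outputs: dict[str, str] = {}
    inputs: dict[str, str] = {}
    stage = "configuration"
    try:
        stage = "read_tree"
        tree_path = resolve(cfg["tree"])
        inputs["tree"] = _digest(tree_path)
        fmt = "nexus" if tree_path.endswith((".nex", ".nexus")) else "newick"
        phylo = treemod.read_tree(tree_path, fmt)

        stage = "read_pathway"
        if "pathway_compounds" in cfg:
            cpath, epath = resolve(cfg["pathway_compounds"]), resolve(cfg["pathway_edges"])
            inputs["pathway_compounds"] = _digest(cpath)
            inputs["pathway_edges"] = _digest(epath)
            dag = load_pathway(cpath, epath)
        else:
            dag = load_default_pathway()

        stage = "read_occurrences"
        occ_path = resolve(cfg["occurrences"])
        inputs["occurrences"] = _digest(occ_path)
        records = coding.read_occurrences(occ_path, dag)
        missing = set(phylo.tip_labels) - set(records)
        for tip in missing:
            records[tip] = coding.ChemOccurrence(tip)

        stage = "code_characters"
        stage_char = {t: coding.code_stage_character(records[t], dag) for t in phylo.tip_labels}
        class_char = {
            t: coding.code_class_character(records[t], cfg["class_policy"])
            for t in phylo.tip_labels
        }
        complexity = {
            t: float(coding.complexity_score(records[t], dag)) for t in phylo.tip_labels
        }
        p1 = os.path.join(outdir, "character_stage.tsv")
        coding.write_discrete_character(stage_char, p1)
        p2 = os.path.join(outdir, "character_class.tsv")
        coding.write_discrete_character(class_char, p2)
        p3 = os.path.join(outdir, "character_complexity.tsv")
        coding.write_continuous_character(complexity, p3)
        for p in (p1, p2, p3):
            outputs[os.path.basename(p)] = p

        stage = "fit_stage_character"
        stage_space = mk.StateSpace(coding.STAGE_STATES)
        stage_fits, stage_best = _fit_character(
            phylo, stage_char, stage_space, cfg["stage_models"], root,
            int(cfg["n_restarts"]), seed, alpha, "stage", outdir, outputs,
        )

        stage = "fit_class_character"
        class_space = mk.StateSpace(tuple(str(i) for i in range(1, 8)))
        class_data = {
            t: (frozenset(str(s) for s in v) if isinstance(v, frozenset) else str(v))
            for t, v in class_char.items()
        }
        class_fits, class_best = _fit_character(
            phylo, class_data, class_space, cfg["class_models"], root,
            int(cfg["n_restarts"]), seed, alpha, "class", outdir, outputs,
        )

        stage = "ancestral_states_discrete"
        threshold = float(cfg["threshold"])
        for label, fits, best, data in (
            ("stage", stage_fits, stage_best, stage_char),
            ("class", class_fits, class_best, class_data),
        ):
            rec = mk.marginal_ancestral_states(
                phylo, data, fits[best].model, root, threshold=threshold
            )
            table = rec.to_table(phylo)
            tpath = os.path.join(outdir, f"{label}_asr.tsv")
            treemod.write_node_table(table, tpath)
            outputs[os.path.basename(tpath)] = tpath
            npath = os.path.join(outdir, f"{label}_asr.nex")
            ann = table[[c for c in table.columns if c.startswith("p_")]].copy()
            ann.columns = [c.replace(" ", "_") for c in ann.columns]
            treemod.write_annotated_tree(phylo, ann, npath)
            outputs[os.path.basename(npath)] = npath

        stage = "ancestral_states_continuous"
        bmfit = bm.bm_ancestral_states(phylo, complexity)
        btable = bmfit.to_table(phylo)
        bpath = os.path.join(outdir, "complexity_asr.tsv")
        treemod.write_node_table(btable, bpath)
        outputs[os.path.basename(bpath)] = bpath
        painting = bm.paint_branches(phylo, bmfit, int(cfg.get("paint_steps", 10)))
        ppath = os.path.join(outdir, "complexity_painting.tsv")
        painting.to_table().to_csv(ppath, sep="\t", index=False)
        outputs[os.path.basename(ppath)] = ppath

        stage = "summary"
        lines = [
            f"defchem {defchem.__version__} analysis summary",
            f"tree: {cfg['tree']} ({phylo.n_tips} tips)",
            f"root treatment: {root}; reporting threshold: {threshold}",
            "",
            f"stage character best model (sequential LRT, alpha={alpha}): {stage_best}",
            *(
                f"  {m}: logL={stage_fits[m].log_likelihood:.4f} "
                f"params={stage_fits[m].n_params} AIC={stage_fits[m].aic:.4f}"
                for m in stage_fits
            ),
            "",
            f"class character best model: {class_best}",
            *(
                f"  {m}: logL={class_fits[m].log_likelihood:.4f} "
                f"params={class_fits[m].n_params} AIC={class_fits[m].aic:.4f}"
                for m in class_fits
            ),
            "",
            f"complexity BM fit: sigma2={bmfit.sigma2:.6f} "
            f"root estimate={bmfit.root_estimate:.4f}"
            + (" (negative ancestral estimates present)" if bmfit.has_negative_estimates else ""),
        ]
        spath = os.path.join(outdir, "summary.txt")
        with open(spath, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        outputs[os.path.basename(spath)] = spath
    except DefchemError as exc:
        raise DefchemError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        inputs=inputs,
        seed=seed,
        version=defchem.__version__,
        parameters={k: v for k, v in cfg.items() if k != "out_dir"},
        outputs={name: _digest(path) for name, path in outputs.items()},
    )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json() + "\n")
    return outdir
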