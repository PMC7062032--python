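"""Configuration, validation and orchestration of the analysis stages.

A pipeline run is fully described by a config mapping (YAML on disk):
which stages to run, subset flags, thresholds, file paths, and one explicit
seed per stochastic stage. Outputs are deterministic given config + seeds
and each result bundle embeds a provenance block (config hash + package
version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assemblage import (ACTIVITY_CLASSES, COLOUR_VOCABULARY, VISION_CLASSES,
                         build_assemblage, filter_units, transform_variables,
                         _split_colours)
from .nullgradient import permutation_test, progressive_delimitation
from .pathsem import PathModel, backward_eliminate
from .synthdata import (LandscapeSpec, StructuralScenario, generate_landscape,
                        generate_palm_flora, generate_primate_assemblage,
                        save_inputs)

logger = logging.getLogger("palmvision")

_STOCHASTIC_STAGES = ("simulate", "permute")

DEFAULT_CONFIG = {
    "stages": ["simulate", "assemble", "sem"],
    "subset": "all",
    "focal_class": "richness_trichromat",
    "min_palatable_palms": 3,
    "alpha": 0.05,
    "seeds": {},
    "simulate": {"n_units": 200, "n_palm_species": 60,
                 "conspicuous_gradient": 1.0, "effect": 0.5},
    "sem": {"formulas": "richness_trichromat ~ prop_conspicuous + temp + prec"
                        " + tseas + pseas"},
    "permute": {"reps": 200, "focal_path": ["prop_conspicuous",
                                            "richness_trichromat"]},
    "gradient": {"min_threshold": 2, "max_threshold": 16},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (cfg or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    for stage in merged["stages"]:
        if stage in _STOCHASTIC_STAGES and stage not in merged["seeds"]:
            raise ValueError(f"stochastic stage {stage!r} requires an explicit "
                             "seed in config['seeds']")
    return merged


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def validate_tables(units=None, palm_traits=None, primate_traits=None,
                    occ_palms=None, occ_primates=None) -> list:
    """Schema/vocabulary/referential-integrity report; empty list = clean."""
    problems = []
    if primate_traits is not None:
        bad = set(primate_traits["vision_system"]) - set(VISION_CLASSES)
        problems += [f"unknown vision_system: {v}" for v in sorted(bad)]
        bad = set(primate_traits["activity"]) - set(ACTIVITY_CLASSES)
        problems += [f"unknown activity: {v}" for v in sorted(bad)]
        bad = set(primate_traits["frugivory_rank"]) - {0, 1, 2, 3}
        problems += [f"frugivory_rank out of range: {v}" for v in sorted(bad)]
    if palm_traits is not None and "colours" in palm_traits.columns:
        for sid, col in zip(palm_traits["species_id"], palm_traits["colours"]):
            unknown = _split_colours(col) - COLOUR_VOCABULARY
            for tok in sorted(unknown):
                problems.append(f"unknown colour token {tok!r} for {sid}")
    if units is not None:
        if units["unit_id"].duplicated().any():
            problems.append("duplicate unit_id in unit table")
        if "area" in units.columns and (units["area"] <= 0).any():
            problems.append("non-positive area in unit table")
    for occ, traits, what in ((occ_palms, palm_traits, "palm"),
                              (occ_primates, primate_traits, "primate")):
        if occ is None:
            continue
        if traits is not None:
            miss = set(occ["species_id"]) - set(traits["species_id"])
            problems += [f"{what} occurrence references unknown species {s}"
                         for s in sorted(miss)]
        if units is not None:
            miss = set(occ["unit_id"]) - set(units["unit_id"])
            problems += [f"{what} occurrence references unknown unit {u}"
                         for u in sorted(miss)]
    return problems


def run_pipeline(cfg: dict, outdir=None) -> dict:
    """Run the configured stages; returns the result bundle.

    Deterministic given config + seeds; the bundle's ``provenance`` block
    records the config hash and package version.
    """
    cfg = validate_config(cfg)
    bundle = {"provenance": {"config_hash": config_hash(cfg),
                             "version": __version__, "config": cfg}}
    data = {}

    if "simulate" in cfg["stages"]:
        seed = int(cfg["seeds"]["simulate"])
        sim = cfg["simulate"]
        logger.info("simulate: n_units=%s seed=%s", sim["n_units"], seed)
        units = generate_landscape(LandscapeSpec(n_units=sim["n_units"],
                                                 seed=seed))
        palm_traits, palm_occ = generate_palm_flora(
            units, n_species=sim["n_palm_species"],
            conspicuous_gradient=sim["conspicuous_gradient"], seed=seed + 1)
        scenario = StructuralScenario(path_coefficients={
            ("prop_conspicuous", cfg["focal_class"]): sim["effect"]})
        primate_traits, primate_occ = generate_primate_assemblage(
            units, palm_traits, palm_occ, scenario, seed=seed + 2)
        data.update(units=units, palm_traits=palm_traits, palm_occ=palm_occ,
                    primate_traits=primate_traits, primate_occ=primate_occ)
        problems = validate_tables(units, palm_traits, primate_traits,
                                   palm_occ, primate_occ)
        if problems:
            raise ValueError("generated tables failed validation: "
                             + "; ".join(problems[:5]))
        if outdir is not None:
            save_inputs(Path(outdir) / "inputs", units, palm_traits, palm_occ,
                        primate_traits, primate_occ, params=sim)

    if "assemble" in cfg["stages"]:
        table = build_assemblage(data["primate_occ"], data["palm_occ"],
                                 data["primate_traits"], data["palm_traits"],
                                 data["units"], subset=cfg["subset"])
        table = filter_units(table, focal_class=cfg["focal_class"],
                             min_palatable_palms=cfg["min_palatable_palms"])
        data["assemblage"] = table
        bundle["assemblage_n_units"] = len(table)
        if outdir is not None:
            table.to_csv(Path(outdir) / "assemblage.csv", index=False)

    if "sem" in cfg["stages"]:
        from .pathsem import _parse_formulas

        variables, _ = _parse_formulas(cfg["sem"]["formulas"])
        trans, _ = transform_variables(data["assemblage"], columns=variables,
                                       sqrt_columns=(cfg["focal_class"],),
                                       log_columns=("area",))
        model = PathModel.from_formulas(cfg["sem"]["formulas"], trans)
        res, log = backward_eliminate(model, alpha=cfg["alpha"])
        bundle["sem"] = {"paths": res.paths.to_dict("records"),
                         "indices": res.fit_indices(),
                         "elimination_log": log}
        data["sem_results"] = res
        if outdir is not None:
            res.paths.to_csv(Path(outdir) / "sem_paths.csv", index=False)
            (Path(outdir) / "sem_indices.json").write_text(
                json.dumps(_jsonable(res.fit_indices()), indent=2))

    if "permute" in cfg["stages"]:
        seed = int(cfg["seeds"]["permute"])
        pr = permutation_test(
            data["units"], data["palm_traits"], data["palm_occ"],
            data["primate_traits"], data["primate_occ"],
            cfg["sem"]["formulas"], tuple(cfg["permute"]["focal_path"]),
            reps=cfg["permute"]["reps"], seed=seed, subset=cfg["subset"],
            min_palatable_palms=cfg["min_palatable_palms"])
        bundle["permutation"] = {"observed": pr.observed,
                                 "quantile": pr.quantile,
                                 "significant": pr.significant}
    if "gradient" in cfg["stages"]:
        gr = progressive_delimitation(
            data["assemblage"], cfg["sem"]["formulas"],
            tuple(cfg["permute"]["focal_path"]),
            thresholds=range(cfg["gradient"]["min_threshold"],
                             cfg["gradient"]["max_threshold"] + 1))
        bundle["gradient"] = gr.table.to_dict("records")
        if outdir is not None:
            gr.table.to_csv(Path(outdir) / "gradient.csv", index=False)

    if outdir is not None:
        (Path(outdir) / "bundle.json").write_text(
            json.dumps(_jsonable(bundle), indent=2))
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    return obj
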