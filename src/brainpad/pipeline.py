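"""End-to-end pipeline orchestration from a single config.

Stages run in a fixed order -- simulate (or load), harmonize, brain age,
difference maps, receptor association, PLS transcriptomics, enrichment --
each seeded from a per-stage sub-seed derived deterministically from the
config seed, so any stage can be re-run in isolation.  Every produced file is
recorded in a manifest with its SHA-256 content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import brainage, enrich, groupmaps, harmonize, io, mapstats, syndata, txpls
from .syndata import ThicknessParams

logger = logging.getLogger(__name__)

STAGES = ("simulate", "combat", "brainage", "tmap", "spatial", "pls", "enrich")

TEST_PROFILE_CAPS = {"n_perm": 199, "n_surr": 199, "n_boot": 200}

_INPUT_KEYS = ("cohort", "features", "geometry", "receptors", "expression",
               "genesets", "risk_genes")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Either ``simulate`` holds generator parameters, or ``inputs`` maps the
    seven input tables to existing files.  ``profile='test'`` caps n_perm and
    n_surr at 199 and n_boot at 200.
    """

    seed: int
    outdir: str
    profile: str = "test"
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    stages: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "results")),
            profile=str(raw.get("profile", "test")),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            stages=dict(raw.get("stages", {})),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        if self.profile not in ("test", "full"):
            raise ValueError(f"profile must be 'test' or 'full', got {self.profile!r}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must provide exactly one of 'simulate' or 'inputs'")
        if self.inputs is not None:
            missing_keys = [k for k in _INPUT_KEYS if k not in self.inputs]
            if missing_keys:
                raise ValueError(f"inputs missing entries: {missing_keys}")
            for key in _INPUT_KEYS:
                p = Path(self.inputs[key])
                if not p.exists():
                    raise ValueError(f"input file for {key!r} does not exist: {p}")
        unknown = set(self.stages) - set(STAGES[1:])
        if unknown:
            raise ValueError(f"unknown stage config key(s): {sorted(unknown)}")

    def stage_param(self, stage: str, key: str, default):
        value = self.stages.get(stage, {})
        if isinstance(value, bool):
            return default
        value = value.get(key, default)
        if self.profile == "test" and key in TEST_PROFILE_CAPS:
            value = min(int(value), TEST_PROFILE_CAPS[key])
        return value

    def stage_enabled(self, stage: str) -> bool:
        value = self.stages.get(stage, True)
        if isinstance(value, bool):
            return value
        return bool(value.get("enabled", True))


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31): the first state word of
    ``SeedSequence(seed, spawn_key=(stage index,))``."""
    ss = np.random.SeedSequence(seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all enabled stages; returns (and writes) the artifact manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    summary: dict[str, Any] = {}

    def emit_table(df, name, index=True):
        path = out / name
        io.write_table(df, path, index=index)
        produced.append(path)
        return path

    def run_stage(name, fn):
        try:
            logger.info("stage %s: start (seed=%d)", name, stage_seed(config.seed, name))
            fn()
            logger.info("stage %s: done", name)
        except Exception as e:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    state: dict[str, Any] = {}

    # ---- simulate / load -------------------------------------------------
    def _simulate():
        if config.inputs is not None:
            state["cohort"] = io.read_cohort(config.inputs["cohort"])
            state["features"] = io.read_features(config.inputs["features"])
            state["geometry"] = io.read_geometry(config.inputs["geometry"])
            state["receptors"] = io.read_table(config.inputs["receptors"])
            state["expression"] = io.read_table(config.inputs["expression"])
            state["genesets"] = enrich.read_gmt(config.inputs["genesets"])
            state["risk_genes"] = io.read_risk_genes(config.inputs["risk_genes"])
            state["truth"] = None
            return
        sim = dict(config.simulate or {})
        seed = stage_seed(config.seed, "simulate")
        geometry = syndata.make_geometry(int(sim.get("n_regions", 176)), seed=seed)
        cohort = syndata.make_cohort(
            n_hc=int(sim.get("n_hc", 180)),
            n_mdd=int(sim.get("n_mdd", 120)),
            n_sites=int(sim.get("n_sites", 5)),
            age_range=tuple(sim.get("age_range", (18.0, 80.0))),
            seed=seed + 1,
        )
        tparams = ThicknessParams(**sim.get("thickness", {}))
        if tparams.n_age_regions > geometry.n_regions:
            tparams = ThicknessParams(**{**sim.get("thickness", {}),
                                         "n_age_regions": geometry.n_regions // 2})
        features, truth = syndata.simulate_thickness(cohort, geometry, tparams,
                                                     seed=seed + 2)
        receptors = syndata.simulate_receptor_maps(geometry, truth, seed=seed + 3)
        expr_cfg = sim.get("expression", {})
        expression, risk_genes, genesets = syndata.simulate_expression(
            geometry,
            truth,
            n_genes=int(expr_cfg.get("n_genes", 1000)),
            n_signal=int(expr_cfg.get("n_signal", 30)),
            loading=float(expr_cfg.get("loading", 1.0)),
            noise_sd=float(expr_cfg.get("noise_sd", 0.5)),
            n_terms=int(expr_cfg.get("n_terms", 50)),
            seed=seed + 4,
        )
        state.update(
            cohort=cohort, features=features, geometry=geometry, truth=truth,
            receptors=receptors, expression=expression, risk_genes=risk_genes,
            genesets=genesets,
        )
        inputs_dir = out / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        io.write_cohort(cohort, inputs_dir / "cohort.tsv")
        io.write_features(features, inputs_dir / "features.tsv")
        io.write_geometry(geometry, inputs_dir / "geometry.tsv")
        io.write_table(receptors, inputs_dir / "receptors.tsv")
        io.write_table(expression, inputs_dir / "expression.tsv")
        genesets.to_gmt(inputs_dir / "genesets.gmt")
        io.write_risk_genes(risk_genes, inputs_dir / "risk_genes.txt")
        produced.extend(sorted(inputs_dir.iterdir()))

    run_stage("simulate", _simulate)
    cohort: pd.DataFrame = state["cohort"]
    features: pd.DataFrame = state["features"]
    geometry = state["geometry"]
    meta = cohort.set_index("subject_id")
    design = meta[["age", "sex"]].to_numpy(dtype=float)

    # ---- harmonize -------------------------------------------------------
    def _combat():
        model = harmonize.fit_combat(features, site=meta["site"].to_numpy(),
                                     design=design)
        state["features_combat"] = harmonize.apply_combat(
            model, features, site=meta["site"].to_numpy(), design=design
        )
        emit_table(state["features_combat"], "features_combat.tsv")
        path = out / "combat_model.json"
        model.to_json(path)
        produced.append(path)

    if config.stage_enabled("combat"):
        run_stage("combat", _combat)
    else:
        state["features_combat"] = features

    # ---- brain age -------------------------------------------------------
    def _brainage():
        seed = stage_seed(config.seed, "brainage")
        use_combat = config.stage_param("brainage", "use_combat_features", False)
        feats = state["features_combat"] if use_combat else features
        frac = float(config.stage_param("brainage", "train_fraction_hc", 0.5))
        C = float(config.stage_param("brainage", "C", 1.0))
        eps = float(config.stage_param("brainage", "epsilon", 0.1))
        n_perm = int(config.stage_param("brainage", "n_perm", 199))
        shuffle = config.stage_param("brainage", "shuffle", "train_ages")

        train_ids, test_ids = brainage.split_cohort(cohort, frac, seed=seed)
        model = brainage.train_brainage(
            feats.loc[train_ids], meta.loc[train_ids, "age"], C=C, epsilon=eps
        )
        state["brainage_model"] = model
        pad = brainage.predict_and_pad(model, feats.loc[test_ids],
                                       meta.loc[test_ids, "age"])
        test_groups = meta.loc[test_ids, "group"].to_numpy()
        hc_mask = test_groups == "HC"
        pad_hc = brainage.predict_and_pad(model, feats.loc[test_ids][hc_mask],
                                          meta.loc[test_ids, "age"][hc_mask])
        gd = brainage.compare_groups(pad.brain_pad, test_groups)
        perm = brainage.permutation_null_pad(
            feats, meta["age"], meta["group"], (train_ids, test_ids),
            n_perm=n_perm, seed=seed + 1, shuffle=shuffle, C=C, epsilon=eps,
        )
        pred = pd.DataFrame(
            {
                "subject_id": test_ids,
                "age": meta.loc[test_ids, "age"].to_numpy(),
                "group": test_groups,
                "predicted_age": pad.predicted_age,
                "brain_pad": pad.brain_pad,
            }
        )
        emit_table(pred, "predictions.tsv", index=False)
        emit_table(
            pd.DataFrame({"null_mean_difference": perm.null}),
            "null_distribution.tsv", index=False,
        )
        gd_payload = {
            "t_statistic": gd.t_statistic,
            "p_value": gd.p_value,
            "cohens_d": gd.cohens_d,
            "d_ci_low": gd.d_ci_low,
            "d_ci_high": gd.d_ci_high,
            "mean_difference_years": gd.mean_difference_years,
            "permutation_p": perm.p_value,
            "pearson_r_test": pad.pearson_r,
            "pearson_r_test_hc": pad_hc.pearson_r,
            "mae_years_test": pad.mae_years,
            "mae_years_test_hc": pad_hc.mae_years,
            "n_train": int(len(train_ids)),
            "n_test": int(len(test_ids)),
        }
        _write_json(gd_payload, out / "groupdiff.json")
        produced.append(out / "groupdiff.json")
        model_payload = {
            "feature_names": model.feature_names_in_,
            "coef": model.coef_.tolist(),
            "intercept": model.intercept_,
            "mean": model.mean_.tolist(),
            "scale": model.scale_.tolist(),
            "dropped_features": model.dropped_features_,
            "C": C,
            "epsilon": eps,
        }
        _write_json(model_payload, out / "model.json")
        produced.append(out / "model.json")
        summary["brainage"] = gd_payload

    if config.stage_enabled("brainage"):
        run_stage("brainage", _brainage)

    # ---- difference maps -------------------------------------------------
    def _tmap():
        q = float(config.stage_param("tmap", "q", 0.05))
        groups = meta["group"].to_numpy()
        tmap_combat = groupmaps.roi_ttest_map(state["features_combat"], groups,
                                              q_threshold=q)
        tmap_reg = groupmaps.regression_tmap(
            features, groups, meta[["age", "sex", "site"]], q_threshold=q
        )
        state["tmap"] = tmap_combat
        emit_table(tmap_combat.to_frame(), "tmap_combat.tsv", index=False)
        emit_table(tmap_reg.to_frame(), "tmap_regression.tsv", index=False)
        valid = ~(tmap_combat.excluded | tmap_reg.excluded)
        from scipy import stats as _st

        cross_r = float(_st.pearsonr(tmap_combat.t[valid], tmap_reg.t[valid]).statistic)
        payload = {
            "cross_method_pearson_r": cross_r,
            "n_significant_combat": int(tmap_combat.significant.sum()),
            "n_significant_regression": int(tmap_reg.significant.sum()),
        }
        model = state.get("brainage_model")
        if model is not None and model.feature_names_in_ == list(features.columns):
            weights = pd.Series(model.coef_, index=features.columns)
            r, p = groupmaps.correlate_weights_tmap(weights, tmap_combat)
            k = min(60, len(features.columns))
            count, overlap = groupmaps.top_feature_overlap(
                weights, pd.Series(tmap_combat.significant, index=features.columns), k
            )
            payload.update(
                weight_tmap_r=r, weight_tmap_p=p,
                top_feature_overlap_k=k, top_feature_overlap=count,
                top_feature_overlap_regions=overlap,
            )
        _write_json(payload, out / "tmap_summary.json")
        produced.append(out / "tmap_summary.json")
        summary["tmap"] = payload

    if config.stage_enabled("tmap"):
        run_stage("tmap", _tmap)

    # ---- receptor association -------------------------------------------
    def _spatial():
        seed = stage_seed(config.seed, "spatial")
        n_surr = int(config.stage_param("spatial", "n_surr", 199))
        q = float(config.stage_param("spatial", "q", 0.05))
        mask = config.stage_param("spatial", "mask", "all")
        assoc = mapstats.map_association(
            state["tmap"], state["receptors"], geometry,
            n_surr=n_surr, seed=seed, q_threshold=q, mask=mask,
        )
        emit_table(assoc, "associations.tsv", index=False)
        summary["spatial"] = {
            "n_maps": int(len(assoc)),
            "n_significant": int((assoc["q"] < q).sum()),
        }

    if config.stage_enabled("spatial"):
        run_stage("spatial", _spatial)

    # ---- PLS transcriptomics --------------------------------------------
    def _pls():
        seed = stage_seed(config.seed, "pls")
        n_comp = int(config.stage_param("pls", "n_components", 1))
        n_perm = int(config.stage_param("pls", "n_perm", 199))
        n_boot = int(config.stage_param("pls", "n_boot", 200))
        expression = state["expression"]
        y = pd.Series(state["tmap"].t, index=state["tmap"].region_ids).loc[
            expression.index
        ]
        res = txpls.fit_pls1(expression, y, n_components=n_comp)
        p_comp = txpls.pls_spatial_permutation(
            expression, y, geometry, n_perm=n_perm, seed=seed, n_components=n_comp
        )
        ranking = txpls.bootstrap_gene_weights(expression, y, n_boot=n_boot,
                                               seed=seed + 1)
        risk_ranked, unknown = txpls.rank_risk_genes(ranking, state["risk_genes"])
        state["gene_ranking"] = ranking
        emit_table(ranking, "gene_ranking.tsv", index=False)
        emit_table(risk_ranked, "risk_gene_ranking.tsv", index=False)
        payload = {
            "varexp_y": res.varexp_y.tolist(),
            "p_component": p_comp.tolist(),
            "n_boot": n_boot,
            "n_perm": n_perm,
            "unknown_risk_genes": unknown,
        }
        _write_json(payload, out / "pls_summary.json")
        produced.append(out / "pls_summary.json")
        summary["pls"] = payload

    if config.stage_enabled("pls"):
        run_stage("pls", _pls)

    # ---- enrichment ------------------------------------------------------
    def _enrich():
        q = float(config.stage_param("enrich", "q", 0.05))
        background = list(state["expression"].columns)
        query = [g for g in state["risk_genes"] if g in set(background)]
        result = enrich.hypergeom_enrichment(query, state["genesets"], background,
                                             q_threshold=q)
        emit_table(result, "enrichment.tsv", index=False)
        summary["enrich"] = {
            "n_terms_tested": int(len(result)),
            "n_significant": int(result["significant"].sum()) if len(result) else 0,
        }

    if config.stage_enabled("enrich"):
        run_stage("enrich", _enrich)

    # ---- manifest --------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "profile": config.profile,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "summary": summary,
        "files": {
            str(p.relative_to(out)): {"sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in sorted(set(produced))
        },
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
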