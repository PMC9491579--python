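"""Configuration-driven orchestration of the full analysis.

A YAML config names the inputs (genotypes, allc calls, annotations, line
metadata, a priori gene list) or asks for a simulated bundle, toggles the
stages, and sets every stage parameter.  ``run_pipeline`` executes
phenotyping -> kinship/REML -> scans (univariate, conditional, optional
MTMM) -> enrichment -> allele analysis, and writes a manifest recording the
config hash, derived stage seeds, package version, and per-stage output
checksums, which suffices to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as mio
from .alleles import (
    PermutationSpec,
    clinal_test,
    cumulative_counts,
    epistasis_insertion_test,
    orient_alleles,
    variance_explained_r2,
)
from .enrichment import assign_gene_pvalues, enrichment_curve, rotation_significance
from .lmm import association_scan, bonferroni_threshold, compute_kinship, snp_heritability
from .methylation import feature_levels, line_average
from .mtmm import mtmm_scan
from .simulate import SimulationConfig, write_fixture_bundle
from .utils import derive_seed

__all__ = ["validate_config", "run_pipeline", "ConfigError", "StageError", "DEFAULTS"]


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``errors`` lists every problem."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid config:\n" + "\n".join(f"- {e}" for e in self.errors))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")


DEFAULTS: dict = {
    "inputs": {
        "genotypes": None,  # VCF or genotype TSV
        "allc": None,
        "annotations": None,
        "phenotypes": None,  # line metadata / precomputed traits
        "apriori": None,
        "simulate": False,  # generate the fixture bundle instead of reading
    },
    "stages": {
        "phenotype": True,
        "scan": True,
        "enrich": True,
        "alleles": True,
        "mtmm": False,
    },
    "params": {
        "maf_min": 0.05,
        "window": 15000,
        "grid_min": 1.0,
        "grid_max": 12.0,
        "grid_step": 0.25,
        "n_rotations": 3000,
        "n_perm": 3000,
        "context": "CHG",
        "covariate_context": "CHH",
        "n_focal": 5,
        "alpha": 0.05,
        "exact": False,
    },
    "seed": 0,
    "out_dir": "results",
}

_REQUIRED_WHEN_NOT_SIMULATED = ("genotypes", "annotations", "allc", "apriori", "phenotypes")


def _merge(defaults: dict, user: dict, errors: list, prefix: str = "") -> dict:
    out = {}
    for k, v in defaults.items():
        if isinstance(v, dict):
            out[k] = _merge(v, user.get(k, {}) or {}, errors, prefix + k + ".")
        else:
            out[k] = user.get(k, v)
    for k in user:
        if k not in defaults:
            errors.append(f"unknown key: {prefix}{k}")
    return out


def validate_config(source) -> dict:
    """Validate and normalize a config (path, YAML text, or dict).

    Unknown keys are rejected; defaults are filled in and echoed back.
    All problems are aggregated into a single :class:`ConfigError`.
    Normalization is idempotent: ``validate_config(validate_config(c)) ==
    validate_config(c)``.
    """
    if isinstance(source, dict):
        user = source
    else:
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError(["config must be a YAML mapping"])
    errors: list[str] = []
    cfg = _merge(DEFAULTS, user, errors)

    if not cfg["inputs"]["simulate"]:
        for key in _REQUIRED_WHEN_NOT_SIMULATED:
            path = cfg["inputs"][key]
            if path is None:
                errors.append(f"inputs.{key} is required unless inputs.simulate is true")
            elif not Path(path).exists():
                errors.append(f"inputs.{key}: path does not exist: {path}")
    pr = cfg["params"]
    if not (0.0 <= pr["maf_min"] < 0.5):
        errors.append("params.maf_min must be in [0, 0.5)")
    if pr["window"] < 0:
        errors.append("params.window must be >= 0")
    for k in ("n_rotations", "n_perm", "n_focal"):
        if int(pr[k]) < 1:
            errors.append(f"params.{k} must be >= 1")
    if cfg["stages"]["enrich"] and not cfg["stages"]["scan"]:
        errors.append("stages.enrich requires stages.scan")
    if cfg["stages"]["alleles"] and not cfg["stages"]["scan"]:
        errors.append("stages.alleles requires stages.scan")
    if errors:
        raise ConfigError(errors)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config, log=print) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    cfg = validate_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    pr = cfg["params"]
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seeds": {},
        "stages": {},
        "outputs": {},
    }

    def _stage_done(name: str, t0: float, files: dict) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        for label, path in files.items():
            manifest["outputs"][f"{name}:{label}"] = {
                "path": str(path),
                "sha256": _sha256(Path(path)),
            }
        log(f"[{name}] done in {manifest['stages'][name]['seconds']}s")

    # ---- inputs -----------------------------------------------------------
    t0 = time.time()
    if cfg["inputs"]["simulate"]:
        sim_seed = derive_seed(seed, "simulate")
        manifest["seeds"]["simulate"] = sim_seed
        sim_cfg = SimulationConfig(seed=sim_seed)
        from .simulate import clinal_config

        sim_cfg = clinal_config(seed=sim_seed)
        bundle = write_fixture_bundle(sim_cfg, out_dir / "fixture")
        paths = {k: Path(v) for k, v in bundle.items()}
        _stage_done("simulate", t0, bundle)
    else:
        paths = {
            "vcf": Path(cfg["inputs"]["genotypes"]),
            "allc": Path(cfg["inputs"]["allc"]),
            "annotations": Path(cfg["inputs"]["annotations"]),
            "phenotypes": Path(cfg["inputs"]["phenotypes"]),
            "apriori": Path(cfg["inputs"]["apriori"]),
        }

    try:
        if str(paths.get("matrix", "")).endswith(".tsv") and Path(paths.get("matrix", "")).exists():
            geno = mio.read_genotype_tsv(paths["matrix"])
        elif str(paths["vcf"]).endswith(".vcf"):
            geno = mio.read_vcf(paths["vcf"])
        else:
            geno = mio.read_genotype_tsv(paths["vcf"])
        meta = mio.read_phenotypes(paths["phenotypes"])
        feats = mio.read_bed(paths["annotations"])
        apriori = mio.read_gene_list(paths["apriori"])
    except Exception as exc:  # noqa: BLE001 - surfaced with a machine-readable code
        raise StageError("inputs", "E_DATA", str(exc)) from exc
    tes = [f for f in feats if f.kind == "TE"]
    genes = [f for f in feats if f.kind == "gene"]

    # ---- phenotyping ------------------------------------------------------
    if cfg["stages"]["phenotype"]:
        t0 = time.time()
        try:
            calls = mio.read_allc(paths["allc"])
            lv = feature_levels(calls, tes, context=pr["context"])
            te_levels_path = out_dir / "te_levels.tsv"
            pd.DataFrame(
                {"feature": list(lv), "level": [np.nan if v is None else v for v in lv.values()]}
            ).to_csv(te_levels_path, sep="\t", index=False)
            manifest["phenotype_line_average"] = line_average(lv)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("phenotype", "E_DATA", str(exc)) from exc
        _stage_done("phenotype", t0, {"te_levels": te_levels_path})

    if not cfg["stages"]["scan"]:
        for dep in ("enrich", "alleles"):
            if cfg["stages"][dep]:
                raise StageError(dep, "E_DEPENDENCY", "requires the scan stage")
        _write_manifest(manifest, out_dir)
        return manifest

    # ---- kinship, REML, scans --------------------------------------------
    t0 = time.time()
    try:
        for col in ("trait1", "trait2"):
            if col not in meta.columns:
                raise StageError("scan", "E_DATA", f"phenotypes table lacks column {col}")
        y_cov = meta["trait1"].to_numpy(float)  # mCHH-like covariate
        y = meta["trait2"].to_numpy(float)  # mCHG-like focal trait
        K = compute_kinship(geno)
        h2 = snp_heritability(y, K)
        uni = association_scan(y, geno, K, maf_min=pr["maf_min"], exact=pr["exact"])
        cond = association_scan(
            y, geno, K, covariate=y_cov, maf_min=pr["maf_min"], exact=pr["exact"]
        )
        scan_paths = {}
        for name, res in (("univariate", uni), ("conditional", cond)):
            sp = out_dir / f"scan_{name}.tsv"
            res.table.assign(model=res.model).to_csv(sp, sep="\t", index=False)
            scan_paths[name] = sp
        manifest["snp_heritability"] = float(h2)
        manifest["bonferroni_p"] = bonferroni_threshold(cond, alpha=pr["alpha"])
        if cfg["stages"]["mtmm"]:
            mt = mtmm_scan(y_cov, y, geno, K, maf_min=pr["maf_min"], seed=derive_seed(seed, "mtmm"))
            for name in ("any", "common", "specific"):
                sp = out_dir / f"scan_mtmm_{name}.tsv"
                mt[name].table.assign(model=mt[name].model).to_csv(sp, sep="\t", index=False)
                scan_paths[f"mtmm_{name}"] = sp
            manifest["mtmm_genetic_correlation"] = float(mt["null"].genetic_correlation)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("scan", "E_NUMERIC", str(exc)) from exc
    _stage_done("scan", t0, scan_paths)

    # ---- enrichment -------------------------------------------------------
    if cfg["stages"]["enrich"]:
        t0 = time.time()
        try:
            grid = np.arange(pr["grid_min"], pr["grid_max"] + 1e-9, pr["grid_step"])
            gp = assign_gene_pvalues(cond, genes, apriori, window=pr["window"])
            rot_seed = derive_seed(seed, "rotation")
            manifest["seeds"]["rotation"] = rot_seed
            enr = rotation_significance(
                gp, grid, n_rotations=pr["n_rotations"], seed=rot_seed
            )
            ep = out_dir / "enrichment.tsv"
            tab = enr.table.copy()
            tab["rotation_p"] = enr.rotation_p
            tab.to_csv(ep, sep="\t", index=False)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrich", "E_NUMERIC", str(exc)) from exc
        _stage_done("enrich", t0, {"enrichment": ep})

    # ---- allele analysis --------------------------------------------------
    if cfg["stages"]["alleles"]:
        t0 = time.time()
        try:
            top = cond.table.nsmallest(int(pr["n_focal"]), "p_value")
            focal_idx = top["snp_index"].to_numpy()
            focal = orient_alleles(cond, focal_idx)
            counts = cumulative_counts(geno, focal)
            r2 = variance_explained_r2(y, geno, focal_idx)
            perm_seed = derive_seed(seed, "perm")
            manifest["seeds"]["perm"] = perm_seed
            spec = PermutationSpec(n_perm=pr["n_perm"], seed=perm_seed)
            allele_out = {
                "focal_snps": [int(i) for i in focal_idx],
                "variance_explained_r2": float(r2),
            }
            if "longitude" in meta.columns:
                cl = clinal_test(geno, focal, meta["longitude"].to_numpy(float), spec)
                allele_out["clinal_r"] = cl["r_obs"]
                allele_out["clinal_p"] = cl["p_value"]
            if "insertion_count" in meta.columns:
                partner = int(
                    cond.table.loc[~cond.table["snp_index"].isin(focal_idx)]
                    .nsmallest(1, "p_value")["snp_index"]
                    .iloc[0]
                )
                ep_tab = epistasis_insertion_test(
                    meta["insertion_count"].to_numpy(float), geno, partner, focal, spec
                )
                ep_path = out_dir / "epistasis.tsv"
                ep_tab.to_csv(ep_path, sep="\t", index=False)
                allele_out["partner_snp"] = partner
            ap = out_dir / "alleles.json"
            ap.write_text(json.dumps(allele_out, indent=1, sort_keys=True))
            pd.DataFrame({"line_id": geno.line_ids, "count": counts}).to_csv(
                out_dir / "allele_counts.tsv", sep="\t", index=False
            )
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("alleles", "E_NUMERIC", str(exc)) from exc
        _stage_done("alleles", t0, {"alleles": ap, "counts": out_dir / "allele_counts.tsv"})

    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
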