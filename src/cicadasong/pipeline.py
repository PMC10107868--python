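"""Full-analysis orchestration: inputs -> signal / PGLS / model-ledger /
morphospace reports.

The pipeline reconciles the species sets of tree, trait table and
ecological table (trimming the tree, aborting with an exhaustive list
of mismatches), then runs, in order: phylogenetic-signal estimation
(Pagel's lambda per continuous trait, Fritz-Purvis D per binary
habitat trait), the single-predictor PGLS battery, the seven-model
trait-evolution comparison per acoustic variable with habitat regime
paintings, and the acoustic phylomorphospace.  Reports are written as
TSV (floats at 3 decimals) plus JSON (full precision) together with a
run manifest (seed, config echo, content hash); identical config and
seed give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .eco import dichotomize_midrange
from .evomodels import (ancestral_discrete_marginal, fit_multi_regime,
                        fit_single_regime, model_comparison, paint_regimes)
from .morphospace import pca_species_traits, phylomorphospace
from .pgls import TransformPolicy, pgls_battery
from .physignal import fritz_purvis_d, pagel_lambda_signal
from .simulate import (SimulationSpec, simulate_continuous, simulate_individuals,
                       simulate_eco_table, simulate_tree, threshold_binary)
from .tree import PhyloTree, drop_tips, parse_newick, write_newick

__all__ = ["PipelineConfig", "run_full_analysis", "write_reports",
           "synthetic_study"]

ACOUSTIC = ("CD", "NE", "ER", "ED", "ID", "DF")
TEMPORAL = ("CD", "NE", "ER", "ED", "ID")

# Study-shaped transformed-scale Brownian rates and ancestral values used by
# the packaged synthetic spec (trait -> (sigma2, z0)).
_SYNTH_TRAITS = {
    "CD": (0.15, 1.4),
    "NE": (0.50, 1.5),
    "ER": (0.60, 2.0),
    "ED": (0.45, -3.0),
    "ID": (0.84, -2.6),
    "DF": (0.08, 3.5),   # sqrt scale, DF in kHz
    "PL": (0.05, 2.08),  # log scale, mm
}


@dataclass
class PipelineConfig:
    tree_path: str | None = None
    traits_path: str | None = None
    eco_path: str | None = None
    out_dir: str = "cicadasong_out"
    seed: int = 0
    n_sim_d: int = 1000
    lambda_bounds: tuple[float, float] = (0.0, 1.0)
    n_starts: int = 5
    # deterministic resolution for exact 0.5/0.5 ancestral-state marginals
    # when painting regimes (None = abort on ties)
    regime_tie_state: int | None = 0
    strict: bool = False
    run_signal: bool = True
    run_pgls: bool = True
    run_models: bool = True
    run_morphospace: bool = True

    def validate(self) -> None:
        paths = [self.tree_path, self.traits_path, self.eco_path]
        if any(paths) and not all(paths):
            raise ValueError("supply all of tree/traits/eco paths or none "
                             "(none = packaged synthetic study)")
        if self.n_sim_d < 10:
            raise ValueError("n_sim_d too small for stable D p-values")


# ---------------------------------------------------------------------------
# Synthetic study inputs (packaged 14-species study-shaped setup)


def synthetic_study(spec: SimulationSpec | None = None) -> dict:
    """Generate the complete input bundle the pipeline consumes.

    Returns dict with ``tree`` (PhyloTree), ``traits`` (species-indexed
    means/SEs for CD..DF and PL) and ``eco`` (species-indexed bioclim
    columns, mean NDVI and calling-site class), all deterministic under
    the spec seed.
    """
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    tree = simulate_tree(spec.n_tips, spec.birth_rate, seed=spec.seed)
    species = tree.tip_labels

    traits = pd.DataFrame(index=pd.Index(species, name="species"))
    for var, (s2, z0) in _SYNTH_TRAITS.items():
        sub_seed = int(rng.integers(2**31))
        m_t = simulate_continuous(tree, "BM", {"sigma2": s2, "z0": z0},
                                  seed=sub_seed)
        raw = np.exp(m_t) if var != "DF" else m_t**2
        # within-species spread proportional to the mean (constant CV)
        frames = [
            simulate_individuals({sp: m}, within_sd=spec.within_sd * m,
                                 n_per_species=spec.n_per_species,
                                 seed=int(rng.integers(2**31)))
            for sp, m in zip(species, raw)
        ]
        ind = pd.concat(frames, ignore_index=True)
        agg = ind.groupby("species")["value"]
        traits[f"{var}_mean"] = agg.mean()
        traits[f"{var}_se"] = agg.std(ddof=1) / np.sqrt(spec.n_per_species)

    # Habitat: calling site from a rank-thresholded Brownian trait, NDVI as a
    # squashed Brownian trait dichotomized at mid-range by the pipeline.
    site_latent = simulate_continuous(tree, "BM", {"sigma2": 1.0, "z0": 0.0},
                                      seed=int(rng.integers(2**31)))
    shrubby = threshold_binary(site_latent, spec.n_shrubby)
    ndvi_latent = simulate_continuous(tree, "BM", {"sigma2": 1.0, "z0": 0.0},
                                      seed=int(rng.integers(2**31)))
    ndvi = 0.45 + 0.25 * np.tanh(ndvi_latent)

    n_bio = 19
    blocks = np.eye(n_bio)
    for a in range(0, 9, 3):  # three correlated triples among the 19
        for i in range(a, a + 3):
            for j in range(a, a + 3):
                if i != j:
                    blocks[i, j] = 0.9
    bio = simulate_eco_table(blocks, n_rows=len(species),
                             seed=int(rng.integers(2**31)),
                             var_names=[f"bio{i+1}" for i in range(n_bio)])
    bio.index = pd.Index(species, name="species")

    eco = bio.copy()
    eco["ndvi"] = ndvi
    eco["calling_site"] = np.where(shrubby == 1, "shrubby", "arboreal")
    return {"tree": tree, "traits": traits, "eco": eco,
            "spec": spec}


# ---------------------------------------------------------------------------
# Orchestration


def _reconcile(tree: PhyloTree, traits: pd.DataFrame, eco: pd.DataFrame
               ) -> PhyloTree:
    t_sp, tr_sp, ec_sp = set(tree.tip_labels), set(traits.index), set(eco.index)
    problems = []
    for name, s in (("trait table", tr_sp), ("eco table", ec_sp)):
        missing = sorted(s - t_sp)
        if missing:
            problems.append(f"species in {name} but not in tree: {missing}")
    if tr_sp != ec_sp:
        problems.append(
            f"trait/eco species mismatch: only-traits={sorted(tr_sp - ec_sp)} "
            f"only-eco={sorted(ec_sp - tr_sp)}")
    if problems:
        raise ValueError("species reconciliation failed: " + "; ".join(problems))
    extra = t_sp - tr_sp
    return drop_tips(tree, extra) if extra else tree


def _delta_se(var: str, mean: float, se: float, policy: TransformPolicy) -> float:
    """Standard error on the transformed scale (delta method)."""
    how = policy.transform_name(var)
    if how == "log":
        return se / mean
    if how == "sqrt":
        return se / (2.0 * np.sqrt(mean))
    return se


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run every configured stage and write the report bundle."""
    config.validate()
    if config.tree_path:
        tree = parse_newick(Path(config.tree_path).read_text())
        traits = pd.read_csv(config.traits_path, index_col="species")
        eco = pd.read_csv(config.eco_path, index_col="species")
    else:
        bundle = synthetic_study(SimulationSpec(seed=config.seed))
        tree, traits, eco = bundle["tree"], bundle["traits"], bundle["eco"]

    tree = _reconcile(tree, traits, eco)
    species = tree.tip_labels
    traits = traits.loc[species]
    eco = eco.loc[species]
    policy = TransformPolicy()

    ndvi_class, ndvi_cut = dichotomize_midrange(eco["ndvi"])
    site_code = {s: int(eco.loc[s, "calling_site"] == "shrubby") for s in species}
    ndvi_code = {s: int(ndvi_class[s] == "high") for s in species}
    bio_cols = [c for c in eco.columns if c.startswith("bio")]

    results: dict = {"species": species, "ndvi_cutoff": ndvi_cut}

    cont_vars = [v for v in (*ACOUSTIC, "PL") if f"{v}_mean" in traits.columns]

    if config.run_signal:
        rows = []
        for var in cont_vars:
            x = policy.apply(var, traits[f"{var}_mean"].to_numpy())
            sig = pagel_lambda_signal(tree, dict(zip(species, x)),
                                      bounds=config.lambda_bounds)
            rows.append({"trait": policy.label(var), "lambda": sig.lambda_,
                         "p": sig.pvalue, "D": np.nan, "pRandom": np.nan,
                         "pBrownian": np.nan})
        for name, code in (("Calling site", site_code), ("NDVI", ndvi_code)):
            d = fritz_purvis_d(tree, code, n_sim=config.n_sim_d,
                               seed=config.seed)
            rows.append({"trait": name, "lambda": np.nan, "p": np.nan,
                         "D": d.D, "pRandom": d.p_random,
                         "pBrownian": d.p_brownian})
        results["signal"] = pd.DataFrame(rows)

    if config.run_pgls:
        resp = traits[[f"{v}_mean" for v in ACOUSTIC if f"{v}_mean" in traits]]
        resp.columns = [c[:-5] for c in resp.columns]
        preds = eco[bio_cols].copy()
        if "PL_mean" in traits:
            preds.insert(0, "PL", traits["PL_mean"])
        preds["NDVI"] = pd.Series(ndvi_code)
        preds["CallingSite"] = pd.Series(site_code)
        results["pgls"] = pgls_battery(tree, resp, preds, policy=policy)

    if config.run_models:
        site_probs, _ = ancestral_discrete_marginal(tree, site_code)
        ndvi_probs, _ = ancestral_discrete_marginal(tree, ndvi_code)
        paint_site = paint_regimes(tree, site_probs,
                                   regime_names=("arboreal", "shrubby"),
                                   tie_state=config.regime_tie_state)
        paint_ndvi = paint_regimes(tree, ndvi_probs,
                                   regime_names=("low", "high"),
                                   tie_state=config.regime_tie_state)
        ledger_rows = []
        full_fits: dict = {}
        acoustic_vars = [v for v in ACOUSTIC if f"{v}_mean" in traits.columns]
        for var in acoustic_vars:
            m = traits[f"{var}_mean"].to_numpy(dtype=float)
            s = traits[f"{var}_se"].to_numpy(dtype=float)
            x = policy.apply(var, m)
            se_t = np.array([_delta_se(var, mi, si, policy)
                             for mi, si in zip(m, s)])
            fits = {}
            for mod in ("BM", "OU", "EB"):
                fits[mod] = fit_single_regime(tree, x, se_t, model=mod,
                                              n_starts=config.n_starts,
                                              seed=config.seed)
            for label, paint in (("site", paint_site), ("ndvi", paint_ndvi)):
                for mod in ("BMS", "OUMV"):
                    fits[f"{mod}_{label}"] = fit_multi_regime(
                        tree, x, se_t, painting=paint, model=mod,
                        n_starts=config.n_starts, seed=config.seed)
            comp = model_comparison(fits)
            tab = comp.table.copy()
            tab.insert(0, "trait", policy.label(var))
            tab["best"] = tab["model"] == comp.best_model
            tab["strong_support"] = comp.strong_support
            ledger_rows.append(tab)
            full_fits[policy.label(var)] = {
                name: {"params": _jsonable(f.params), "loglik": f.loglik,
                       "k": f.k, "aicc": f.aicc, "boundary": f.boundary}
                for name, f in fits.items()
            }
        results["models"] = pd.concat(ledger_rows, ignore_index=True)
        results["model_fits"] = full_fits
        results["paintings"] = {
            "site": paint_site.branch_regime.tolist(),
            "ndvi": paint_ndvi.branch_regime.tolist(),
        }

    if config.run_morphospace:
        temporal = pd.DataFrame(
            {v: policy.apply(v, traits[f"{v}_mean"].to_numpy())
             for v in TEMPORAL if f"{v}_mean" in traits.columns},
            index=traits.index)
        loadings, scores, pct = pca_species_traits(temporal, standardize=True)
        proj = phylomorphospace(tree, scores)
        results["morphospace"] = {
            "loadings": loadings, "scores": scores, "percent_variance": pct,
            "node_scores": proj.node_scores, "edges": proj.edges,
        }

    results["tree_newick"] = write_newick(tree)
    manifest = write_reports(results, config)
    results["manifest"] = manifest
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_reports(results: dict, config: PipelineConfig) -> dict:
    """Write TSV/JSON reports and the run manifest; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def tsv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.3f")
        written.append(p)

    def jsn(payload, name: str) -> None:
        p = out / name
        p.write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True))
        written.append(p)

    if "signal" in results:
        tsv(results["signal"], "signal.tsv")
        jsn(results["signal"].to_dict(orient="records"), "signal.json")
    if "pgls" in results:
        tsv(results["pgls"], "pgls.tsv")
        jsn(results["pgls"].to_dict(orient="records"), "pgls.json")
    if "models" in results:
        tsv(results["models"], "models.tsv")
        jsn(results["model_fits"], "model_fits.json")
    if "morphospace" in results:
        ms = results["morphospace"]
        tsv(ms["scores"].reset_index(), "morphospace_scores.tsv")
        jsn({"loadings": ms["loadings"].to_dict(),
             "percent_variance": ms["percent_variance"].tolist(),
             "node_scores": ms["node_scores"].tolist(),
             "edges": [list(e) for e in ms["edges"]]},
            "morphospace.json")
    (out / "tree.nwk").write_text(results["tree_newick"])
    written.append(out / "tree.nwk")

    h = hashlib.sha256()
    for p in sorted(written):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    manifest = {
        "package": "cicadasong",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config": _jsonable(asdict(config)),
        "content_sha256": h.hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
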