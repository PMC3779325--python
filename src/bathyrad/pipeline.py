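"""Orchestration: run the analysis stages (simulate/prepare ->
diversification -> mass-extinction test -> state-dependent speciation ->
comparative battery) from one configuration, with seeds recorded and all
artifacts written as plain TSV/JSON/Newick."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import phylo, simulate, diversification, mass_extinction, bisse, comparative

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prepare", "diversification", "extinction_test", "sse",
          "comparative")

DEFAULT_CONFIG = {
    "seed": 1,
    "output_dir": "bathyrad_out",
    "tree": None,
    "traits": None,
    "preset": "mussel",
    "stages": list(STAGES),
    "prepare": {"support_threshold": 0.0},
    "diversification": {"replicates": 200, "fraction_missing": 0.0,
                        "criterion": "aicc"},
    "extinction_test": {"age": 57.0, "survival": 0.05, "replicates": 100},
    "sse": {"character": "methanotroph", "sampling": [1.0, 1.0]},
    "comparative": {"anova_sims": 1000, "pagel_sims": 100,
                    "pagel_restarts": 2},
}


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if key not in DEFAULT_CONFIG:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    return cfg


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages in dependency order; returns the run
    record (also written to ``run_record.json``).  Completed-stage artifacts
    survive a downstream failure."""
    cfg = merge_config(config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    record: dict = {"config": cfg, "version": __version__, "stages": {},
                    "seed": seed}
    tree = traits = None
    if cfg["tree"]:
        tree = phylo.read_newick(cfg["tree"])
        record["tree_sha"] = _sha(Path(cfg["tree"]))
    if cfg["traits"]:
        traits = phylo.read_traits(cfg["traits"])
        record["traits_sha"] = _sha(Path(cfg["traits"]))

    def need_tree(stage):
        if tree is None:
            raise RuntimeError(
                f"stage '{stage}' needs a tree: supply one or enable the "
                "simulate stage"
            )

    try:
        if "simulate" in cfg["stages"] and tree is None:
            preset = simulate.mussel_preset()
            tree = simulate.simulate_tree(preset, rng)
            traits = simulate.mussel_trait_table(tree, rng)
            phylo.write_newick(tree, str(out / "synthetic_tree.nwk"))
            phylo.write_traits(traits, str(out / "synthetic_traits.tsv"))
            record["stages"]["simulate"] = {
                "preset": cfg["preset"],
                "n_tips": sum(1 for _ in tree.leaf_node_iter()),
            }
        if "prepare" in cfg["stages"]:
            need_tree("prepare")
            tree, traits, prov = phylo.prepare_tree(
                tree, traits,
                support_threshold=cfg["prepare"]["support_threshold"],
            )
            record["stages"]["prepare"] = prov
        if "diversification" in cfg["stages"]:
            need_tree("diversification")
            bt = phylo.branching_times(tree)
            fits = diversification.model_selection_table(bt)
            df = diversification.fits_to_dataframe(fits)
            df.to_csv(out / "diversification_models.tsv", sep="\t",
                      index=False, float_format="%.6g")
            dcfg = cfg["diversification"]
            res = diversification.shift_test(
                bt, replicates=int(dcfg["replicates"]),
                fraction_missing=float(dcfg["fraction_missing"]),
                seed=rng, criterion=dcfg["criterion"],
            )
            record["stages"]["diversification"] = {
                "best_model": min(fits, key=lambda f: f.aic).name,
                "shift_statistic": res.statistic,
                "shift_p": res.p_value,
            }
            wfit, cfit, chi2, p = diversification.fit_weibull_window(bt, 41.0)
            record["stages"]["diversification"]["weibull"] = {
                "beta": wfit.params["beta"], "chi2": chi2, "p": p,
            }
        if "extinction_test" in cfg["stages"]:
            need_tree("extinction_test")
            ecfg = cfg["extinction_test"]
            res = mass_extinction.me_extinction_test(
                tree, t_me=float(ecfg["age"]), rho=float(ecfg["survival"]),
                replicates=int(ecfg["replicates"]), seed=rng,
            )
            pd.DataFrame({
                "null_delta": res.null_deltas, "alt_delta": res.alt_deltas,
            }).to_csv(out / "extinction_test_deltas.tsv", sep="\t", index=False)
            pd.DataFrame({
                "age": res.ltt_ages,
                "h0_lo": res.h0_envelope[0], "h0_hi": res.h0_envelope[1],
                "h1_lo": res.h1_envelope[0], "h1_hi": res.h1_envelope[1],
            }).to_csv(out / "extinction_test_ltt.tsv", sep="\t", index=False)
            record["stages"]["extinction_test"] = {
                "delta_observed": res.delta_observed, "p": res.p_value,
                "rejection_level": res.rejection_level,
            }
        if "sse" in cfg["stages"]:
            need_tree("sse")
            if traits is None:
                raise RuntimeError("stage 'sse' needs a trait table")
            char = cfg["sse"]["character"]
            sub = traits.dropna(subset=[char])
            if char == "symbiont_location":
                states = {
                    r["species"]: int(r[char] == "intracellular")
                    for _, r in sub.iterrows()
                }
            else:
                states = {r["species"]: int(r[char]) for _, r in sub.iterrows()}
            stree = phylo.clone_tree(tree)
            stree.retain_taxa_with_labels(list(states))
            stree.purge_taxon_namespace()
            res = bisse.fit_sse_models(
                stree, states, sampling=tuple(cfg["sse"]["sampling"])
            )
            pd.DataFrame([{
                "character": char, "lambda0": res.lam0, "lambda1": res.lam1,
                "lambda_yule": res.lam_yule, "LR": res.lr, "p": res.p_value,
            }]).to_csv(out / "sse_test.tsv", sep="\t", index=False,
                       float_format="%.6g")
            record["stages"]["sse"] = {
                "character": char, "LR": res.lr, "p": res.p_value,
                "lambda0": res.lam0, "lambda1": res.lam1,
            }
        if "comparative" in cfg["stages"]:
            need_tree("comparative")
            if traits is None:
                raise RuntimeError("stage 'comparative' needs a trait table")
            ccfg = cfg["comparative"]
            results = []
            tdf = traits.set_index("species", drop=False)
            tips = [l.taxon.label for l in tree.leaf_node_iter()]
            tdf = tdf.loc[[t for t in tips if t in tdf.index]]
            shell = tdf.dropna(subset=["shell_length_mm"])
            logsize = {
                s: float(np.log(v)) for s, v in
                shell["shell_length_mm"].items()
            }
            habitat = tdf["habitat"].dropna().to_dict()
            pooled = comparative.pooled_habitat(
                tdf["habitat"].dropna()).to_dict()
            # ANOVA: log(size) ~ habitat
            common = sorted(set(logsize) & set(habitat))
            if len(set(habitat[s] for s in common)) >= 2:
                r = comparative.phylo_anova(
                    tree, logsize, habitat, sims=int(ccfg["anova_sims"]),
                    seed=rng,
                )
                results.append(("pAnova", "log(size) ~ habitat", r))
            # Pagel: methanotroph ~ pooled habitat
            if "methanotroph" in tdf:
                meth = tdf["methanotroph"].dropna().astype(int).to_dict()
                hab_bin = {s: int(h == "vent+seep") for s, h in pooled.items()}
                common = sorted(set(meth) & set(hab_bin))
                x = {s: meth[s] for s in common}
                y = {s: hab_bin[s] for s in common}
                if len(set(x.values())) == 2 and len(set(y.values())) == 2:
                    r = comparative.pagel_correlation_test(
                        tree, x, y, restarts=int(ccfg["pagel_restarts"]),
                        sims=int(ccfg["pagel_sims"]), seed=rng,
                    )
                    results.append(("Pagel", "methanotroph ~ habitat", r))
            # PGLS: log(size) ~ mid depth
            depth = tdf.dropna(subset=["depth_min_m", "depth_max_m"])
            mid = {
                s: float(0.5 * (r_["depth_min_m"] + r_["depth_max_m"]))
                for s, r_ in depth.iterrows()
            }
            if len(set(logsize) & set(mid)) >= 4:
                r = comparative.pgls_fit(tree, logsize, mid)
                results.append(("pGLS", "log(size) ~ depth", r))
            # Mann-Whitney: vent/seep vs organic-fall depths
            grp_a = [mid[s] for s in mid if pooled.get(s) == "vent+seep"]
            grp_b = [mid[s] for s in mid if pooled.get(s) == "organic-fall"]
            if grp_a and grp_b:
                r = comparative.mann_whitney_depth(grp_a, grp_b)
                results.append(("MannWhitney", "depth ~ habitat", r))
            rows = []
            for model, variables, r in results:
                rows.append({
                    "model": model, "variables": variables,
                    "species": r.n_species,
                    "criterion": "; ".join(
                        f"{k}={v:.4g}" for k, v in r.statistic.items()),
                    "df": "; ".join(f"{k}={v}" for k, v in r.df.items()),
                    "p_value": r.p_value, "phylogenetic_p": r.p_phylo,
                })
            pd.DataFrame(rows).to_csv(out / "comparative_tests.tsv", sep="\t",
                                      index=False)
            record["stages"]["comparative"] = {
                "tests": [row["model"] for row in rows]
            }
    finally:
        with open(out / "run_record.json", "w") as fh:
            json.dump(record, fh, indent=2, default=float)
    return record
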