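"""End-to-end orchestration: orthology -> normalization -> descriptive ->
differential expression -> convergence (-> enrichment, methylation).

The pipeline is configured by a YAML file (paths resolved relative to the
config file) and writes deterministic TSV/JSON artifacts plus a run report
with per-stage row counts and sha256 checksums of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import convergence as conv
from . import descriptive, diffexp, enrichment, methylation, normalization, orthology
from .errors import ConfigurationError
from .io_formats import (
    read_count_matrix,
    read_cpg_report,
    read_gene_table,
    read_hit_table,
    read_term_map,
    write_count_matrix,
    write_cpg_report,
    write_gene_table,
    write_hit_table,
)
from .synthetic_data import (
    SimConfig,
    score_calls,
    simulate_counts,
    simulate_hit_tables,
    simulate_methylation,
)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_PARAMS", "load_config", "run_pipeline", "write_synthetic_dataset"]

DEFAULT_PARAMS: dict = {
    "evalue_cutoff": 1e-5,
    "logratio_trim": 0.30,
    "abs_trim": 0.05,
    "reference": "auto",
    "lfc_threshold": 1.0,
    "fdr_threshold": 0.05,
    "dispersion": "auto",
    "min_support": None,
    "include_other_focal": False,
    "log_pseudocount": 1.0,
    "linkage_method": "complete",
    "enrichment_fdr": 0.05,
    "promoter_span": 1000,
    "min_cpg": 2,
    "min_depth_exclusive": 5,
}

_FLOAT_FMT = "%.10g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg["_base_dir"] = path.parent
    _validate_config(cfg)
    return cfg


def _resolve(cfg: dict, p) -> Path:
    p = Path(p)
    return p if p.is_absolute() else Path(cfg.get("_base_dir", ".")) / p


def _validate_config(cfg: dict) -> None:
    if "species" not in cfg or len(cfg["species"]) < 3:
        raise ConfigurationError("config needs >= 3 species (2 focal + background)")
    roles = [sp.get("role") for sp in cfg["species"]]
    if roles.count("focal") != 2:
        raise ConfigurationError(
            f"exactly 2 focal species expected, got {roles.count('focal')}"
        )
    for sp in cfg["species"]:
        for key in ("id", "counts", "genes"):
            if key not in sp:
                raise ConfigurationError(f"species entry missing {key!r}: {sp}")
        for key in ("counts", "genes"):
            p = _resolve(cfg, sp[key])
            if not p.exists():
                raise ConfigurationError(f"missing input file: {p}")
    ids = [sp["id"] for sp in cfg["species"]]
    for sa, sb in combinations(ids, 2):
        fwd_path, rev_path = _hit_paths(cfg, sa, sb)
        for p in (fwd_path, rev_path):
            if not p.exists():
                raise ConfigurationError(f"missing hit table: {p}")


def _hit_paths(cfg: dict, sa: str, sb: str) -> tuple[Path, Path]:
    """Paths of the (sa -> sb, sb -> sa) hit tables, whichever key order the
    config uses for the unordered pair."""
    hits = cfg.get("hits", {})
    entry = hits.get(f"{sa}__{sb}")
    if entry is not None:
        return _resolve(cfg, entry["forward"]), _resolve(cfg, entry["reverse"])
    entry = hits.get(f"{sb}__{sa}")
    if entry is not None:
        return _resolve(cfg, entry["reverse"]), _resolve(cfg, entry["forward"])
    raise ConfigurationError(f"missing hit tables for pair {sa}/{sb}")


def _params(cfg: dict) -> dict:
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params") or {})
    return params


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: dict | str | Path, outdir=None) -> dict:
    """Run every stage; returns the run report (also written as JSON)."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = config
    params = _params(cfg)
    out = Path(outdir) if outdir is not None else _resolve(cfg, cfg.get("outdir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"tissue": cfg.get("tissue", ""), "parameters": params, "stages": {}}
    outputs: list[Path] = []

    # stage ordering puts the two focal species first so the orthologue map
    # is anchored on the first focal species' gene ids
    species_cfg = sorted(cfg["species"], key=lambda sp: 0 if sp.get("role") == "focal" else 1)
    species_ids = [sp["id"] for sp in species_cfg]
    focal = [sp["id"] for sp in species_cfg if sp.get("role") == "focal"]
    tissue = cfg.get("tissue", "")

    # ---- inputs ----------------------------------------------------------
    count_mats = {
        sp["id"]: read_count_matrix(_resolve(cfg, sp["counts"]), sp["id"], tissue)
        for sp in species_cfg
    }
    gene_tables = {sp["id"]: read_gene_table(_resolve(cfg, sp["genes"])) for sp in species_cfg}
    species_of = {
        s: sp for sp, cm in count_mats.items() for s in cm.sample_ids
    }

    # ---- orthology -------------------------------------------------------
    rbh_sets = {}
    for sa, sb in combinations(species_ids, 2):
        fwd_path, rev_path = _hit_paths(cfg, sa, sb)
        fwd = read_hit_table(fwd_path, params["evalue_cutoff"])
        rev = read_hit_table(rev_path, params["evalue_cutoff"])
        rbh_sets[(sa, sb)] = orthology.reciprocal_best_hits(fwd, rev)
    omap = orthology.one_to_one_orthologues(rbh_sets, species_ids, tissue=tissue)
    omap_path = out / "orthologues.tsv"
    orthology.write_orthologue_map(omap, omap_path)
    outputs.append(omap_path)
    report["stages"]["orthology"] = {"n_orthologues": len(omap)}

    # ---- join counts and lengths on orthologue rows ----------------------
    anchor = species_ids[0]
    omap_df = omap.to_frame()
    joined_cols, length_cols, sample_names = [], [], []
    rep_lengths = {}
    for sp in species_ids:
        recs = gene_tables[sp]
        iso = orthology.select_longest_isoform(recs)
        by_iso = {(r.gene_id, r.isoform_id): r for r in recs}
        rep_lengths[sp] = {
            gid: by_iso[(gid, iso_id)].length for gid, iso_id in iso.items()
        }
    for sp in species_ids:
        frame = count_mats[sp].to_frame()
        missing = [g for g in omap_df[sp] if g not in frame.index]
        if missing:
            raise ConfigurationError(
                f"orthologue genes absent from {sp} count matrix: {missing[:5]}..."
            )
        sub = frame.loc[omap_df[sp]].to_numpy()
        joined_cols.append(sub)
        lengths = np.array([rep_lengths[sp][g] for g in omap_df[sp]])
        length_cols.append(np.tile(lengths[:, None], (1, sub.shape[1])))
        sample_names.extend(count_mats[sp].sample_ids)
    joined = pd.DataFrame(
        np.hstack(joined_cols), index=omap_df[anchor], columns=sample_names
    )
    length_matrix = pd.DataFrame(
        np.hstack(length_cols), index=omap_df[anchor], columns=sample_names
    )

    # ---- normalization ---------------------------------------------------
    filtered = normalization.filter_low_expressed(joined, species_of)
    lengths_f = length_matrix.loc[filtered.index]
    tmm_params = normalization.TMMParams(
        logratio_trim=params["logratio_trim"],
        abs_trim=params["abs_trim"],
        reference_sample=params["reference"],
    )
    norm = normalization.getmm_normalize(filtered, lengths_f, tmm_params)
    norm_path = out / "normalized.tsv"
    _write_tsv(norm.values, norm_path)
    factors_path = out / "normalization_factors.json"
    _write_json(
        {
            "tmm_factors": {k: float(v) for k, v in norm.scaling_factors.items()},
            "rpk_library_sizes": {k: float(v) for k, v in norm.library_sizes.items()},
        },
        factors_path,
    )
    outputs += [norm_path, factors_path]
    cv_raw = normalization.coefficient_of_variation(filtered)
    cv_norm = normalization.coefficient_of_variation(norm.values)
    report["stages"]["normalization"] = {
        "n_genes_pre_filter": len(joined),
        "n_genes_post_filter": len(filtered),
        "median_cv_raw": float(cv_raw.median()),
        "median_cv_normalized": float(cv_norm.median()),
    }

    # ---- descriptive -----------------------------------------------------
    logged = descriptive.log_transform(norm.values, params["log_pseudocount"])
    pca_res = descriptive.pca(logged.T)
    pca_path = out / "pca_scores.tsv"
    _write_tsv(pca_res.scores, pca_path)
    var_path = out / "pca_variance.tsv"
    _write_tsv(
        pd.DataFrame(
            {"variance_fraction": pca_res.variance_explained},
            index=pca_res.scores.columns,
        ),
        var_path,
    )
    clustering = descriptive.cluster_samples(logged, method=params["linkage_method"])
    corr_path = out / "spearman_correlation.tsv"
    _write_tsv(clustering.correlation, corr_path)
    newick_path = out / "sample_dendrogram.nwk"
    newick_path.write_text(clustering.newick + "\n")
    outputs += [pca_path, var_path, corr_path, newick_path]
    report["stages"]["descriptive"] = {
        "pc1_variance": float(pca_res.variance_explained[0]),
        "pc2_variance": float(pca_res.variance_explained[1]),
    }

    # ---- differential expression (length-corrected exact test) -----------
    rpk_matrix = normalization.rpk(filtered, lengths_f)
    eff_lib = norm.library_sizes * norm.scaling_factors
    samples_by_species: dict[str, list[str]] = {}
    for s in sample_names:
        samples_by_species.setdefault(species_of[s], []).append(s)

    background_of: dict[str, list[str]] = {}
    for f in focal:
        bg = [sp for sp in species_ids if sp != f]
        if not params["include_other_focal"]:
            bg = [sp for sp in bg if sp not in focal]
        background_of[f] = bg

    de_counts = {}
    deg_sets: dict[str, dict[str, diffexp.DEGSets]] = {f: {} for f in focal}
    for f in focal:
        for other in background_of[f]:
            cols_a = samples_by_species[f]
            cols_b = samples_by_species[other]
            disp = params["dispersion"]
            if disp == "auto":
                sub = rpk_matrix[cols_a + cols_b]
                groups = (
                    list(range(len(cols_a))),
                    list(range(len(cols_a), len(cols_a) + len(cols_b))),
                )
                disp = diffexp.estimate_common_dispersion(
                    sub, groups, lib_sizes=eff_lib[cols_a + cols_b].to_numpy()
                )
            de = diffexp.de_table(
                rpk_matrix[cols_a],
                rpk_matrix[cols_b],
                float(disp),
                eff_lib[cols_a].to_numpy(),
                eff_lib[cols_b].to_numpy(),
                lfc_threshold=params["lfc_threshold"],
                fdr_threshold=params["fdr_threshold"],
            )
            de_path = out / f"de_{f}_vs_{other}.tsv"
            _write_tsv(de, de_path)
            outputs.append(de_path)
            sets = diffexp.call_degs(
                de, params["lfc_threshold"], params["fdr_threshold"]
            )
            deg_sets[f][other] = sets
            de_counts[f"{f}_vs_{other}"] = {
                "dispersion": float(disp),
                "n_up": len(sets.up),
                "n_down": len(sets.down),
            }
    report["stages"]["diffexp"] = de_counts

    # ---- convergence -----------------------------------------------------
    f1, f2 = focal
    shared = {}
    for f in focal:
        shared[f] = {
            "up": conv.shared_degs(
                {sp: deg_sets[f][sp].up for sp in background_of[f]},
                background=background_of[f],
                min_support=params["min_support"],
            ),
            "down": conv.shared_degs(
                {sp: deg_sets[f][sp].down for sp in background_of[f]},
                background=background_of[f],
                min_support=params["min_support"],
            ),
        }
    result = conv.convergent_genes(
        shared[f1]["up"], shared[f1]["down"], shared[f2]["up"], shared[f2]["down"],
        tissue=tissue,
    )
    for name, genes in (
        ("convergent_up", result.convergent_up),
        ("convergent_down", result.convergent_down),
        (f"shared_up_{f1}", result.shared_up_focal1),
        (f"shared_down_{f1}", result.shared_down_focal1),
        (f"shared_up_{f2}", result.shared_up_focal2),
        (f"shared_down_{f2}", result.shared_down_focal2),
    ):
        p = out / f"{name}.txt"
        p.write_text("".join(f"{g}\n" for g in sorted(genes)))
        outputs.append(p)
    conv_summary_path = out / "convergence_summary.json"
    _write_json(result.summary(), conv_summary_path)
    outputs.append(conv_summary_path)
    report["stages"]["convergence"] = result.summary()

    # ---- truth scoring (synthetic runs only) -----------------------------
    if cfg.get("truth"):
        truth_up = set(
            _resolve(cfg, cfg["truth"]["convergent_up"]).read_text().split()
        )
        truth_down = set(
            _resolve(cfg, cfg["truth"]["convergent_down"]).read_text().split()
        )
        report["stages"]["truth_recovery"] = score_calls(
            result.convergent_up, result.convergent_down, truth_up, truth_down
        )

    # ---- enrichment (optional) -------------------------------------------
    if cfg.get("term_map"):
        tm = read_term_map(_resolve(cfg, cfg["term_map"]))
        universe = set(count_mats[f1].gene_ids)
        enr = {}
        for name, genes in (
            ("up", result.convergent_up), ("down", result.convergent_down)
        ):
            table = enrichment.over_representation(genes & universe, tm, universe)
            p = out / f"enrichment_convergent_{name}.tsv"
            _write_tsv(table, p, index=False)
            outputs.append(p)
            enr[name] = {
                "n_terms_tested": len(table),
                "n_significant": int((table["fdr"] < params["enrichment_fdr"]).sum())
                if len(table)
                else 0,
            }
        report["stages"]["enrichment"] = enr

    # ---- methylation (optional) ------------------------------------------
    meth_cfg = cfg.get("methylation")
    if meth_cfg:
        prom_sp = meth_cfg.get("promoter_species", f1)
        recs = gene_tables[prom_sp]
        iso = orthology.select_longest_isoform(recs)
        reps = [
            r for r in recs if iso.get(r.gene_id) == r.isoform_id
        ]
        promoters = methylation.promoter_regions(reps, span=params["promoter_span"])
        all_cpgs = []
        group_levels = {}
        for group in ("group_a", "group_b"):
            cpgs = []
            for sample_id, path in sorted(meth_cfg[group]["reports"].items()):
                cpgs.extend(read_cpg_report(_resolve(cfg, path), sample_id))
            levels, excluded = methylation.promoter_methylation(
                cpgs,
                promoters,
                min_cpg=params["min_cpg"],
                min_depth_exclusive=params["min_depth_exclusive"],
            )
            group_levels[group] = levels
            all_cpgs.append((group, levels, excluded))
        levels_path = out / "promoter_methylation.tsv"
        _write_tsv(
            pd.concat(
                [lv.assign(group=grp) for grp, lv, _ in all_cpgs], ignore_index=True
            ),
            levels_path,
            index=False,
        )
        outputs.append(levels_path)
        dm, skipped = methylation.differential_methylation(
            group_levels["group_a"], group_levels["group_b"]
        )
        dm_path = out / "differential_methylation.tsv"
        _write_tsv(dm, dm_path, index=False)
        outputs.append(dm_path)
        report["stages"]["methylation"] = {
            "n_promoters": len(promoters),
            "n_tested": len(dm),
            "n_significant": int((dm["p_value"] < 0.05).sum()) if len(dm) else 0,
            "n_skipped": len(skipped),
        }

    # ---- report ----------------------------------------------------------
    report["manifest"] = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)
    }
    report_path = out / "run_report.json"
    _write_json(report, report_path)
    return report


# ---------------------------------------------------------------------------
# synthetic dataset materialisation
# ---------------------------------------------------------------------------

def write_synthetic_dataset(config: SimConfig, outdir) -> Path:
    """Simulate a full dataset, write every pipeline input file plus a ready
    pipeline.yaml and truth files; returns the path to the config."""
    out = Path(outdir)
    data = out / "data"
    data.mkdir(parents=True, exist_ok=True)

    matrices, gene_tables, truth = simulate_counts(config)
    species_entries = []
    for i, cm in enumerate(matrices):
        counts_path = data / f"counts_{cm.species}.tsv"
        write_count_matrix(cm, counts_path)
        genes_path = data / f"genes_{cm.species}.tsv"
        write_gene_table(gene_tables[cm.species], genes_path)
        species_entries.append(
            {
                "id": cm.species,
                "role": "focal" if cm.species in config.focal_species else "background",
                "counts": str(counts_path.relative_to(out)),
                "genes": str(genes_path.relative_to(out)),
            }
        )

    hit_tables = simulate_hit_tables(truth, config)
    hits_cfg = {}
    species = config.species_ids
    for i, sa in enumerate(species):
        for sb in species[i + 1 :]:
            fwd_path = data / f"hits_{sa}_{sb}.tsv"
            rev_path = data / f"hits_{sb}_{sa}.tsv"
            write_hit_table(hit_tables[(sa, sb)], fwd_path)
            write_hit_table(hit_tables[(sb, sa)], rev_path)
            hits_cfg[f"{sa}__{sb}"] = {
                "forward": str(fwd_path.relative_to(out)),
                "reverse": str(rev_path.relative_to(out)),
            }

    # promoters for the first focal species' representative isoforms
    f1 = config.focal_species[0]
    iso = orthology.select_longest_isoform(gene_tables[f1])
    reps = [r for r in gene_tables[f1] if iso.get(r.gene_id) == r.isoform_id]
    promoters = methylation.promoter_regions(reps)
    reports, meth_truth = simulate_methylation(config, promoters)
    meth_cfg: dict = {"promoter_species": f1, "group_a": {"reports": {}}, "group_b": {"reports": {}}}
    for sample_id, recs in sorted(reports.items()):
        path = data / f"cpg_{sample_id}.tsv"
        write_cpg_report(recs, path)
        group = "group_a" if sample_id.startswith("methA") else "group_b"
        meth_cfg[group]["reports"][sample_id] = str(path.relative_to(out))
    meth_truth.to_csv(data / "truth_methylation.tsv", sep="\t", index=False)

    up_path = data / "truth_convergent_up.txt"
    down_path = data / "truth_convergent_down.txt"
    up_path.write_text("".join(f"{g}\n" for g in sorted(truth.convergent_up_ids)))
    down_path.write_text("".join(f"{g}\n" for g in sorted(truth.convergent_down_ids)))
    truth.orthology.to_csv(data / "truth_orthology.tsv", sep="\t", index=False)

    cfg = {
        "tissue": config.tissue,
        "seed": config.seed,
        "outdir": "results",
        "species": species_entries,
        "hits": hits_cfg,
        "methylation": meth_cfg,
        "truth": {
            "convergent_up": str(up_path.relative_to(out)),
            "convergent_down": str(down_path.relative_to(out)),
        },
        "params": {},
    }
    cfg_path = out / "pipeline.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path
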