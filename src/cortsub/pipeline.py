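"""End-to-end pipeline orchestration.

Runs rank selection, NMF fit and assignment, follow-up stability,
per-ROI thinning maps, coordinated deformation tests per connectivity
template, gene spatial correlations and over-representation analysis —
serializing every artifact plus a JSON manifest recording the
configuration, derived stage seeds and input checksums.  The manifest
contains no timestamps, so identical configurations produce
byte-identical manifests.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import version, PackageNotFoundError
from pathlib import Path

import numpy as np

from . import io as cio
from .longitudinal import (
    characterize_subtypes,
    stability_analysis,
    thinning_betamaps,
)
from .network import rewire_null, spatial_test
from .subtyping import fit_nmf, invert_thickness, rank_selection
from .transcriptomics import (
    compare_subtype_enrichment,
    gene_significance,
    ora,
    parse_gmt,
)
from .types import CortsubError

logger = logging.getLogger(__name__)


def _pkg_version() -> str:
    try:
        return version("cortsub")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run_pipeline(config: cio.PipelineConfig) -> Path:
    """Execute every stage and return the run directory.

    Any stage failure aborts with the stage name; a partial-results
    manifest listing completed stages is still written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _pkg_version(),
        "config": config.to_dict(),
        "stage_seeds": {s: cio.stage_seed(config.seed, s) for s in cio.STAGE_STREAMS},
        "input_checksums": {},
        "stages_completed": [],
        "results": {},
    }
    stage = "setup"
    try:
        for key in ("thickness", "parcellation", "expression", "gmt"):
            p = getattr(config, key)
            if p:
                manifest["input_checksums"][key] = cio.file_checksum(p)
        for mod, p in config.templates.items():
            manifest["input_checksums"][f"template_{mod}"] = cio.file_checksum(p)

        stage = "load"
        parc = cio.read_parcellation(config.parcellation)
        table = cio.read_thickness(config.thickness, parc)
        templates = {
            mod: cio.read_connectome(p, parc, mod)
            for mod, p in config.templates.items()
        }
        if config.run_genes and not config.expression:
            raise CortsubError("gene stage requested but no expression file configured")

        stage = "rank_selection"
        baseline, subject_ids = table.baseline_matrix()
        X, offsets = invert_thickness(baseline, global_max=config.invert_global_max)
        sub_seed = cio.stage_seed(config.seed, "subtyping")
        if len(config.k_range) > 1:
            report = rank_selection(X, config.k_range, n_restarts=config.n_restarts,
                                    seed=sub_seed)
            k = report.selected_k
            report.to_frame().to_csv(out / "rank_selection.tsv", sep="\t", index=False)
        else:
            k = config.k_range[0]
            logger.info("single-rank k_range; skipping rank selection")
        manifest["results"]["selected_k"] = int(k)
        manifest["stages_completed"].append("rank_selection")

        stage = "fit"
        model = fit_nmf(X, k, n_restarts=config.n_restarts, seed=sub_seed,
                        subject_ids=subject_ids, inversion_offsets=offsets)
        cio.write_model(model, out / "model.json")
        manifest["stages_completed"].append("fit")

        stage = "characterize"
        if model.k == 2:
            char = characterize_subtypes(table, model)
            char.to_csv(out / "subtype_logistic.tsv", sep="\t")
            manifest["stages_completed"].append("characterize")

        stage = "stability"
        stab = stability_analysis(table, model,
                                  use_inverted=config.followup_use_inverted)
        manifest["results"]["krippendorff_alpha"] = float(stab.alpha)
        manifest["results"]["n_unstable"] = int(stab.n_unstable)
        manifest["results"]["n_longitudinal"] = int(len(stab.subject_ids))
        if stab.logistic_table is not None:
            stab.logistic_table.to_csv(out / "stability_logistic.tsv", sep="\t")
        manifest["stages_completed"].append("stability")

        stage = "betamaps"
        maps = thinning_betamaps(table, model)
        cio.write_betamaps(maps, out / "betamaps.tsv")
        manifest["stages_completed"].append("betamaps")

        if config.run_cdm and templates:
            stage = "cdm"
            rewire_seed = cio.stage_seed(config.seed, "rewiring")
            surr_seed = cio.stage_seed(config.seed, "surrogates")
            cdm_out = {}
            for mi, (mod, tpl) in enumerate(sorted(templates.items())):
                rewired = rewire_null(tpl, config.n_perm, seed=rewire_seed + mi)
                for bm in maps:
                    if not np.isfinite(bm.beta).all():
                        continue
                    res = spatial_test(
                        bm, tpl, n_perm=config.n_perm,
                        seed=surr_seed + mi,
                        normalized=config.cdm_normalized,
                        rewired_templates=rewired,
                    )
                    cdm_out[f"{mod}_subtype{bm.subtype_label}"] = {
                        "observed_r": res.observed_r,
                        "p_rewired": res.p_rewired,
                        "p_autocorr": res.p_autocorr,
                        "n_perm": res.n_perm,
                    }
            (out / "cdm.json").write_text(json.dumps(cdm_out, indent=2, sort_keys=True))
            manifest["results"]["cdm"] = cdm_out
            manifest["stages_completed"].append("cdm")

        if config.run_genes:
            stage = "genes"
            expr = cio.read_expression(config.expression)
            gene_seed = cio.stage_seed(config.seed, "genes")
            gene_tables = {}
            for bm in maps:
                if not np.isfinite(bm.beta).all():
                    continue
                gt = gene_significance(
                    bm, expr, parc.distances, n_surr=config.n_surr,
                    alpha_threshold=config.alpha_threshold,
                    seed=gene_seed + bm.subtype_label,
                    two_sided=config.gene_two_sided,
                )
                gt.to_csv(out / f"genes_subtype{bm.subtype_label}.tsv",
                          sep="\t", index=False)
                gene_tables[bm.subtype_label] = gt
                manifest["results"][f"n_significant_genes_subtype{bm.subtype_label}"] = (
                    int(gt["significant"].sum())
                )
            manifest["stages_completed"].append("genes")

            if config.gmt:
                stage = "ora"
                sets = parse_gmt(config.gmt)
                universe = set(expr.gene_symbols)
                enr = {}
                for label, gt in gene_tables.items():
                    query = set(gt.loc[gt["significant"], "symbol"])
                    if query:
                        enr[label] = ora(query, universe, sets)
                if enr:
                    merged = compare_subtype_enrichment(enr)
                    merged.to_csv(out / "ora.tsv", sep="\t", index=False)
                manifest["stages_completed"].append("ora")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        raise CortsubError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
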