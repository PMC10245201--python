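"""End-to-end study pipeline: simulate -> phenotype -> distances -> stats.

Each stage writes its outputs under the run directory and can be resumed
from the intermediates of the previous one. Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import platform
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import StudyConfig
from .distances import (CHARACTERISTICS, characteristic_matrices, combine,
                        minmax_normalize)
from .errors import ConfigurationError, WarnsigError
from .mimicry import mimicry_table, population_members, var_ms_correlation
from .morphospace import classical_mds, density_map, nonmetric_mds, outlier_fraction
from .phenotyping import color_correct, phenotype_image
from .synth import (default_render_spec, generate_phenotypes,
                    head_rasters_from_table, records_from_table, render_frog)
from .variation import (characteristic_var_table, compare_characteristics,
                        rank_characteristics, variance_sum,
                        within_pair_distances)

STAGES = ("simulate", "phenotype", "distances", "mimicry", "morphospace",
          "anatomy")


def _fname(ch: str) -> str:
    return ch.replace(".", "_")


def write_manifest(config: StudyConfig, outdir: Path, outputs: list[str]) -> str:
    ref = config.digest()
    io.write_json({
        "config_hash": ref,
        "seed": config.seed,
        "versions": {"warnsig": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__,
                     "python": platform.python_version()},
        "outputs": sorted(outputs),
    }, outdir / "manifest.json")
    return ref


def run_pipeline(config: StudyConfig, outdir, from_stage: str | None = None,
                 stages=STAGES) -> dict:
    """Run the selected stages, returning in-memory results per stage."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if from_stage is not None:
        if from_stage not in STAGES:
            raise ConfigurationError(f"unknown stage {from_stage!r}")
        stages = STAGES[STAGES.index(from_stage):]
    ref = config.digest()
    opts = config.options
    results: dict = {}
    outputs: list[str] = []

    def stage_error(stage, exc):
        raise WarnsigError(f"stage {stage!r} failed: {exc}") from exc

    # --- simulate -----------------------------------------------------------
    if "simulate" in stages and config.study is not None:
        table = generate_phenotypes(config.study)
        io.write_table(table, outdir / "phenotypes.csv", ref)
        outputs.append("phenotypes.csv")
        results["phenotypes"] = table
        if opts.render_images:
            img_dir = outdir / "images"
            render = default_render_spec()
            for rec in records_from_table(table):
                try:
                    frog = render_frog(rec, render)
                except WarnsigError as e:
                    stage_error("simulate", f"record {rec.individual_id}: {e}")
                io.write_image(frog.raster, img_dir / f"{rec.individual_id}.png")
                io.write_landmarks(frog.landmarks,
                                   img_dir / f"{rec.individual_id}_landmarks.csv")
                io.write_masks(frog.masks,
                               img_dir / f"{rec.individual_id}_masks.png")
            outputs.append("images/")

    # --- phenotype ----------------------------------------------------------
    if "phenotype" in stages:
        table = results.get("phenotypes")
        if table is None:
            src = (outdir / "phenotypes.csv" if config.phenotype_csv is None
                   else config.phenotype_csv)
            table = io.read_table(src)
        if opts.render_images and config.study is not None:
            table, rasters = _phenotype_rendered(table, opts)
            io.write_table(table, outdir / "phenotypes_measured.csv", ref)
            outputs.append("phenotypes_measured.csv")
        else:
            if "jitter_seed" not in table.columns:
                table = table.assign(jitter_seed=0)
            rasters = head_rasters_from_table(table, opts.grid_size)
        io.write_head_rasters(rasters, outdir / "head_rasters.csv", ref)
        outputs.append("head_rasters.csv")
        results["phenotypes_measured"] = table
        results["head_rasters"] = rasters

    # --- distances ----------------------------------------------------------
    if "distances" in stages:
        table = results.get("phenotypes_measured")
        rasters = results.get("head_rasters")
        if table is None:
            measured = outdir / "phenotypes_measured.csv"
            table = io.read_table(measured if measured.exists()
                                  else outdir / "phenotypes.csv")
            rasters = io.read_head_rasters(outdir / "head_rasters.csv")
        mats = characteristic_matrices(table, rasters, opts.hue_mode
                                       if opts.hue_mode != "arithmetic"
                                       else "circular", opts.back_mode)
        norm = {ch: minmax_normalize(m) for ch, m in mats.items()}
        for ch in CHARACTERISTICS:
            io.write_matrix(mats[ch], outdir / "matrices" / f"raw_{_fname(ch)}.csv", ref)
            io.write_matrix(norm[ch], outdir / "matrices" / f"norm_{_fname(ch)}.csv", ref)
        gm = combine([norm[ch] for ch in CHARACTERISTICS])
        io.write_matrix(gm, outdir / "matglob.csv", ref)
        outputs += ["matrices/", "matglob.csv"]
        results["norm_matrices"] = norm
        results["matglob"] = gm
        results["table"] = table

    # --- shared reload for later stages ------------------------------------
    def _need_table_gm():
        if "matglob" not in results:
            results["matglob"] = io.read_global_matrix(outdir / "matglob.csv")
            measured = outdir / "phenotypes_measured.csv"
            results["table"] = io.read_table(
                measured if measured.exists() else outdir / "phenotypes.csv")
        return results["table"], results["matglob"]

    # --- mimicry ------------------------------------------------------------
    if "mimicry" in stages:
        table, gm = _need_table_gm()
        mt = mimicry_table(gm, table, config.sympatry,
                           aggregate=opts.ms_aggregate,
                           method=opts.centroid_method)
        io.write_table(mt, outdir / "mimicry.csv", ref)
        outputs.append("mimicry.csv")
        results["mimicry"] = mt
        pts = mt.drop_duplicates(["species", "locality"])
        if len(pts) >= 3 and np.isfinite(pts["ms"]).all():
            corr = var_ms_correlation(pts["var"], pts["ms"])
            io.write_json({"r": corr.r, "df": corr.df, "p_two_sided": corr.p,
                           "p_one_sided": corr.p_one_sided,
                           "shapiro": corr.shapiro,
                           "warnings": corr.warnings,
                           "n_points": len(pts)},
                          outdir / "correlation.json", ref)
            results["correlation"] = corr
        else:
            warnings.warn("too few (Var, ms) points for a correlation")
            io.write_json({"r": None, "n_points": len(pts)},
                          outdir / "correlation.json", ref)
        outputs.append("correlation.json")

    # --- morphospace --------------------------------------------------------
    if "morphospace" in stages:
        table, gm = _need_table_gm()
        if opts.mds_variant == "nonmetric":
            emb = nonmetric_mds(gm, k=opts.embedding_k, seed=config.seed)
        else:
            emb = classical_mds(gm, k=opts.embedding_k)
        emb_df = pd.DataFrame(
            emb.coordinates,
            columns=[f"dim{i+1}" for i in range(emb.coordinates.shape[1])])
        emb_df.insert(0, "individual_id", gm.labels)
        io.write_table(emb_df, outdir / "embedding.csv", ref)
        outputs.append("embedding.csv")
        keys = list(zip(table["species"], table["locality"]))
        dm = density_map(emb, keys) if emb.coordinates.shape[1] >= 2 else None
        members = population_members(table)
        idx_of = {i: j for j, i in enumerate(gm.labels)}
        rows = []
        for key, ids in members.items():
            others = {k: [idx_of[i] for i in v] for k, v in members.items()
                      if k[0] == key[0] and k != key}
            if not others or len(ids) < 2:
                continue
            frac = outlier_fraction(emb.coordinates,
                                    [idx_of[i] for i in ids], others)
            rows.append({"species": key[0], "locality": key[1],
                         "outlier_fraction": frac, "n": len(ids)})
        out_df = pd.DataFrame(rows)
        io.write_table(out_df, outdir / "outliers.csv", ref)
        outputs.append("outliers.csv")
        results.update(embedding=emb, density=dm, outliers=out_df)
        if opts.plots:
            from .plots import plot_morphospace
            plot_morphospace(emb, keys, dm, outdir / "morphospace.png")
            outputs.append("morphospace.png")

    # --- anatomy ------------------------------------------------------------
    if "anatomy" in stages:
        table, _ = _need_table_gm()
        norm = results.get("norm_matrices")
        if norm is None:
            norm = {ch: io.read_characteristic_matrix(
                outdir / "matrices" / f"norm_{_fname(ch)}.csv", ch, True)
                for ch in CHARACTERISTICS}
        quant = {ch: norm[ch] for ch in CHARACTERISTICS
                 if ch != "classif.pattern"}
        vt = characteristic_var_table(quant, table)
        io.write_table(vt, outdir / "anatomy_var.csv", ref)
        vs = variance_sum(vt, quant, table)
        io.write_table(vs, outdir / "variance_sum.csv", ref)
        groups = within_pair_distances(quant, population_members(table))
        kw = compare_characteristics(groups)
        io.write_json({"h": kw.h, "df": kw.df, "p": kw.p, "note": kw.note,
                       "pairwise": {f"{a}|{b}": kw.pairwise.loc[a, b]
                                    for a in kw.groups for b in kw.groups
                                    if a < b}},
                      outdir / "anatomy_tests.json", ref)
        rk = rank_characteristics(vt)
        io.write_table(rk, outdir / "ranking.csv", ref)
        outputs += ["anatomy_var.csv", "variance_sum.csv",
                    "anatomy_tests.json", "ranking.csv"]
        results.update(anatomy_var=vt, variance_sum=vs, kw=kw, ranking=rk)
        if opts.plots:
            from .plots import plot_variance_sum
            plot_variance_sum(vs, outdir / "variance_sum.png")
            outputs.append("variance_sum.png")

    write_manifest(config, outdir, outputs)
    return results


def _phenotype_rendered(table: pd.DataFrame, opts) -> tuple[pd.DataFrame, dict]:
    """Render every record, colour-correct, and measure it back."""
    render = default_render_spec()
    template = render.landmarks
    rows, rasters = [], {}
    for rec in records_from_table(table):
        try:
            frog = render_frog(rec, render)
            corrected, _ = color_correct(frog)
            measured, raster = phenotype_image(
                corrected, template, rec.pattern_class, rec.individual_id,
                rec.species, rec.locality, grid_size=opts.grid_size,
                threshold=opts.blackness_threshold,
                offset_frac=opts.transect_offset,
                hue_mode=("arithmetic" if opts.hue_mode == "arithmetic"
                          else "circular"))
        except WarnsigError as e:
            raise WarnsigError(
                f"stage 'phenotype' failed on record {rec.individual_id}: {e}"
            ) from e
        row = {k: getattr(measured, k) for k in measured.columns()}
        row["jitter_seed"] = rec.jitter_seed
        rows.append(row)
        rasters[rec.individual_id] = raster
    return pd.DataFrame(rows), rasters
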