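"""End-to-end orchestration: synthetic study generation, per-modality stages,
and cross-scale integration.

File conventions inside a study directory:

* ``annotations.csv`` — one row per product: product, product_set,
  FibreScore, ShearRate, PectinConcentration;
* ``tensile/{product}__{replicate}__{direction}.csv`` with a
  ``tensile/geometry.csv`` sidecar (width/thickness per specimen);
* ``dic/{product}__{direction}__axial.tif`` and ``__transverse.tif``
  multi-page 32-bit float stacks, one page per frame;
* ``tomo/{product}__{replicate}.tif`` uint8 phase stacks (1=solid,
  2=air, 3=rest);
* ``clsm/{product}__{image}.tif`` grayscale micrographs.

Every output table is stamped with the configuration hash, so an
unchanged configuration reproduces outputs byte-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from anisotex import clsm, dic, io, stats, synthetic, tensile, tomo
from anisotex.config import PipelineConfig

logger = logging.getLogger("anisotex")

TENSILE_PARAMS = {
    "YoungsModulus": "youngs_modulus",
    "FractureStress": "fracture_stress",
    "FractureStrain": "fracture_strain",
    "FractureLength": "fracture_length",
    "Toughness": "toughness",
}


class UsageError(RuntimeError):
    """No usable modality found."""


# ---------------------------------------------------------------------------
# synthetic study generation
# ---------------------------------------------------------------------------


def simulate_study(
    outdir: str | Path,
    seed: int = 0,
    n_tensile_replicates: int = 3,
    n_tomo_replicates: int = 2,
    n_clsm_images: int = 3,
    n_dic_frames: int = 15,
    dic_grid: tuple[int, int] = (48, 40),
    tomo_shape: tuple[int, int, int] = (72, 72, 72),
    clsm_shape: tuple[int, int] = (256, 256),
) -> pd.DataFrame:
    """Write a full synthetic two-set study to ``outdir`` and return its metadata.

    Eleven products mimic the study design: one set of five varying in
    shear rate, one set of six varying in pectin concentration (including
    a no-shear control).  A per-product latent anisotropy factor — driven
    by the process variable plus noise — sets the tensile anisotropy, the
    void aspect ratio, the micrograph texture alignment, the strain-field
    heterogeneity and the external fibre score, planting the cross-scale
    correlations the integration stage is meant to recover.
    """
    outdir = Path(outdir)
    geometry_sidecar = outdir / "tensile" / "geometry.csv"
    if geometry_sidecar.exists():  # appended per product; stale copies would duplicate
        geometry_sidecar.unlink()
    rng = np.random.default_rng(seed)
    products = []
    for shear in (0, 20, 39, 65, 130):
        products.append(("MB-%03d" % shear, "MBFF", shear, 0.0))
    products.append(("SP-ns", "SPI", 0, 0.0))
    for pectin in (0.0, 1.0, 2.2, 3.5, 5.0):
        products.append((f"SP-{pectin:g}", "SPI", 39, pectin))

    meta_rows = []
    for product, pset, shear, pectin in products:
        # latent anisotropy in [0, 1]: driven by the set's process variable
        drive = shear / 130.0 if pset == "MBFF" else (0.15 if shear > 0 else 0.0) + pectin / 6.5
        latent = float(np.clip(drive + 0.08 * rng.standard_normal(), 0.0, 1.0))
        _write_product(outdir, product, latent, rng,
                       n_tensile_replicates, n_tomo_replicates, n_clsm_images,
                       n_dic_frames, dic_grid, tomo_shape, clsm_shape)
        fibre_score = 1.0 + 3.0 * latent + 0.15 * rng.standard_normal()
        meta_rows.append(
            {
                "product": product,
                "product_set": pset,
                "FibreScore": fibre_score,
                "ShearRate": shear,
                "PectinConcentration": pectin,
                "latent_true": latent,
            }
        )
    meta = pd.DataFrame(meta_rows)
    outdir.mkdir(parents=True, exist_ok=True)
    meta.drop(columns=["latent_true"]).to_csv(outdir / "annotations.csv", index=False)
    meta.to_csv(outdir / "ground_truth.csv", index=False)
    return meta


def _write_product(
    outdir: Path, product: str, latent: float, rng: np.random.Generator,
    n_tens: int, n_tomo: int, n_clsm: int, n_frames: int,
    dic_grid: tuple[int, int], tomo_shape: tuple[int, int, int],
    clsm_shape: tuple[int, int],
) -> None:
    sub = lambda d: (outdir / d).mkdir(parents=True, exist_ok=True) or (outdir / d)
    tens_dir, dic_dir = sub("tensile"), sub("dic")
    tomo_dir, clsm_dir = sub("tomo"), sub("clsm")

    # tensile: anisotropy ratio grows with the latent factor
    ratio = np.exp(1.2 * latent)
    geo_rows = []
    for direction in ("parallel", "perpendicular"):
        s = np.sqrt(ratio) if direction == "parallel" else 1.0 / np.sqrt(ratio)
        for rep in range(n_tens):
            spec = synthetic.SyntheticTensileSpec(
                youngs_modulus_true=1.8e6 * s,
                fracture_stress_true=1.0e5 * s,
                fracture_strain_true=0.5 * (1.0 + 0.15 * latent),
                softening_span=0.3 * (1.0 + 0.4 * latent * (direction == "parallel")),
                noise_sd=0.01,
                n_points=400,
                seed=int(rng.integers(2**31)),
            )
            record, specimen, _ = synthetic.gen_tensile_curve(spec, direction=direction)
            tag = "par" if direction == "parallel" else "per"
            io.write_tensile_csv(tens_dir / f"{product}__{rep}__{tag}.csv", record)
            geo_rows.append(
                {
                    "product": product, "replicate": rep, "direction": tag,
                    "width0_m": specimen.width0, "thickness0_m": specimen.thickness0,
                    "gauge_length_m": specimen.gauge_length,
                }
            )
    geo_path = tens_dir / "geometry.csv"
    frame = pd.DataFrame(geo_rows)
    if geo_path.exists():
        frame = pd.concat([pd.read_csv(geo_path), frame], ignore_index=True)
    frame.to_csv(geo_path, index=False)

    # DIC: heterogeneity anisotropic in the parallel direction
    for direction, ax_sd, tr_sd in (
        ("par", 0.01 + 0.05 * latent, 0.02 + 0.06 * latent),
        ("per", 0.01 + 0.02 * latent, 0.02 + 0.03 * latent),
    ):
        fspec = synthetic.SyntheticFieldSpec(
            nu_true=0.5,
            nu_final=0.5 - 0.3 * latent,
            n_frames=n_frames,
            grid_shape=dic_grid,
            axial_gradient_sd=ax_sd,
            transverse_gradient_sd=tr_sd,
            seed=int(rng.integers(2**31)),
        )
        series = synthetic.gen_strain_field_series(fspec)
        io.write_stack(dic_dir / f"{product}__{direction}__axial.tif",
                       series.axial.astype(np.float32))
        io.write_stack(dic_dir / f"{product}__{direction}__transverse.tif",
                       series.transverse.astype(np.float32))

    # tomography: bubble elongation follows the latent factor
    for rep in range(n_tomo):
        vspec = synthetic.SyntheticVolumeSpec(
            shape=tomo_shape,
            aspect_ratio=1.0 + 2.0 * latent,
            mean_radius=3.5,
            target_air_fraction=0.010 - 0.004 * latent,
            rest_fraction=0.004,
            placement_jitter=5.0,
            seed=int(rng.integers(2**31)),
        )
        phases, _ = synthetic.gen_void_volume(vspec)
        io.write_stack(tomo_dir / f"{product}__{rep}.tif", phases)

    # CLSM: stripe alignment degraded by noise for low-latent products
    for img in range(n_clsm):
        mspec = synthetic.SyntheticMicrographSpec(
            shape=clsm_shape,
            texture="stripes",
            stripe_angle=0.0,
            noise_amplitude=0.05 + 0.9 * (1.0 - latent),
            n_domains=6,
            domain_aspect=1.0 + 2.0 * latent,
            domain_feret_range=(60.0, 110.0),
            pixel_size=2.0,
            seed=int(rng.integers(2**31)),
        )
        image, _, _ = synthetic.gen_fibrous_micrograph(mspec)
        io.write_stack(clsm_dir / f"{product}__{img}.tif", image.astype(np.float32))


# ---------------------------------------------------------------------------
# per-modality stages
# ---------------------------------------------------------------------------


def stage_tensile(tensile_dir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """Per-specimen tensile summaries from every curve CSV in the directory."""
    tensile_dir = Path(tensile_dir)
    geometry = pd.read_csv(tensile_dir / "geometry.csv")
    geometry = geometry.set_index(["product", "replicate", "direction"])
    rows = []
    for path in sorted(tensile_dir.glob("*__*__*.csv")):
        product, rep, tag = path.stem.split("__")
        geo = geometry.loc[(product, int(rep), tag)]
        specimen = tensile.TensileSpecimen(
            width0=float(geo["width0_m"]),
            thickness0=float(geo["thickness0_m"]),
            gauge_length=float(geo.get("gauge_length_m", config.gauge_length_m)),
            direction="parallel" if tag == "par" else "perpendicular",
        )
        record = io.read_tensile_csv(path)
        curve = tensile.to_true_stress_strain(record, specimen)
        summary = tensile.summarize_curve(
            curve, stress_fraction=config.failure_stress_fraction
        )
        row = {"product": product, "replicate": int(rep), "direction": tag}
        row.update({name: getattr(summary, attr) for name, attr in TENSILE_PARAMS.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_tensile(per_specimen: pd.DataFrame) -> pd.DataFrame:
    """Replicate means per product and direction, plus AIx and SD columns."""
    grouped = per_specimen.groupby(["product", "direction"])
    means = grouped[list(TENSILE_PARAMS)].mean()
    stds = grouped[list(TENSILE_PARAMS)].std()
    products = sorted(per_specimen["product"].unique())
    rows = []
    for product in products:
        row: dict[str, float] = {"product": product}
        for name in TENSILE_PARAMS:
            par = means.loc[(product, "par"), name] if (product, "par") in means.index else np.nan
            per = means.loc[(product, "per"), name] if (product, "per") in means.index else np.nan
            row[f"{name}_par"] = par
            row[f"{name}_per"] = per
            row[f"AIx{name}"] = par / per if per not in (0, np.nan) and pd.notna(per) else np.nan
            for tag in ("par", "per"):
                if (product, tag) in stds.index:
                    row[f"STDEV{name}_{tag}"] = stds.loc[(product, tag), name]
        rows.append(row)
    return pd.DataFrame(rows)


def stage_dic(dic_dir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """Poisson-trace and Moran-slope parameters, one row per product.

    The Moran profile is evaluated on the final (pre-fracture) axial
    frame with within-row adjacency perpendicular to the tensile axis.
    """
    dic_dir = Path(dic_dir)
    per_product: dict[str, dict[str, float]] = {}
    for ax_path in sorted(dic_dir.glob("*__*__axial.tif")):
        product, direction, _ = ax_path.stem.split("__")
        tr_path = dic_dir / f"{product}__{direction}__transverse.tif"
        series = dic.StrainFieldSeries(
            axial=io.read_stack(ax_path),
            transverse=io.read_stack(tr_path),
            axial_axis=0,
            grid_spacing=config.grid_spacing_um,
        )
        trace = dic.poisson_trace(series)
        profile = dic.moran_profile(
            series.axial[-1], axis=config.moran_axis, d_max=config.moran_d_max,
            grid_spacing=config.grid_spacing_um,
        )
        row = per_product.setdefault(product, {"product": product})
        row[f"MoranSlope_{direction}"] = profile.fit_slope
        if direction == "par":
            row["PoissonLinear"] = trace.nu_linear
            row["PoissonFailure"] = trace.nu_failure
            row["PoissonDecrease"] = dic.poisson_decrease(trace)
    frame = pd.DataFrame(sorted(per_product.values(), key=lambda r: r["product"]))
    if {"MoranSlope_par", "MoranSlope_per"} <= set(frame.columns):
        frame["AIxMoranSlope"] = frame["MoranSlope_par"] / frame["MoranSlope_per"]
    return frame


def stage_tomo(tomo_dir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """Per-specimen bubble morphometry summaries from phase volumes."""
    rows = []
    for path in sorted(Path(tomo_dir).glob("*__*.tif")):
        product, rep = path.stem.split("__")
        phases = io.read_stack(path)
        volume = tomo.label_voids(phases, voxel_size=config.voxel_size_um)
        features = tomo.all_bubble_features(volume)
        summary = tomo.specimen_summary(volume, features)
        row = {"product": product, "replicate": int(rep), "NBubbles": summary.n_bubbles}
        row.update(summary.means)
        row["PctAirVolume"] = summary.pct_air_volume
        row["PctRestVolume"] = summary.pct_rest_volume
        rows.append(row)
    return pd.DataFrame(rows)


def stage_clsm(clsm_dir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """Per-image shape and orientation statistics for stained micrographs."""
    rows = []
    for path in sorted(Path(clsm_dir).glob("*__*.tif")):
        product, img = path.stem.split("__")
        micrograph = clsm.Micrograph(
            intensities=io.read_stack(path), pixel_size=config.clsm_pixel_size_um
        )
        adjusted = clsm.auto_contrast(micrograph)
        try:
            threshold = clsm.minimum_threshold(adjusted)
            shapes = clsm.extract_shapes(adjusted, threshold, min_feret=config.min_feret_um)
        except clsm.ThresholdError:
            logger.warning("no bimodal histogram for %s; skipping shapes", path.name)
            shapes = []
        orient = clsm.orientation_coherency(adjusted)
        row = {"product": product, "image": img}
        row.update(clsm.shape_summary(shapes))
        row["Coherency"] = orient.coherency
        row["DominantDirection"] = orient.dominant_direction
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# integration and the full pipeline
# ---------------------------------------------------------------------------


def integrate(
    modalities: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
    config: PipelineConfig,
) -> dict[str, object]:
    """Feature table, variance reports, correlation matrices and selections."""
    table = stats.build_feature_table(modalities, metadata)
    normalized = stats.minmax_normalize(table)
    results: dict[str, object] = {"feature_table": table, "normalized": normalized}
    results["variance_combined"] = stats.parameter_variance(
        normalized, threshold=config.variance_threshold_combined
    )
    results["pearson_combined"] = stats.pearson_matrix(table)
    per_set = stats.per_set_tables(table)
    results["per_set"] = {}
    for label, sub in per_set.items():
        sub_norm = stats.minmax_normalize(sub)
        results["per_set"][label] = {
            "variance": stats.parameter_variance(
                sub_norm, threshold=config.variance_threshold_per_set
            ),
            "pearson": stats.pearson_matrix(sub),
        }
    results["selections"] = {}
    for target in config.selection_targets:
        if target in table.columns:
            results["selections"][target] = stats.univariate_select(
                table, target, k=config.select_k
            )
    return results


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run every stage whose inputs exist and write all report CSVs.

    Raises :class:`UsageError` when no modality directory is present.
    """
    base = Path(config.input_dir) if config.input_dir else None
    resolve = lambda explicit, name: (
        Path(explicit) if explicit else (base / name if base else None)
    )
    tens_dir = resolve(config.tensile_dir, "tensile")
    dic_dir = resolve(config.dic_dir, "dic")
    tomo_dir = resolve(config.tomo_dir, "tomo")
    clsm_dir = resolve(config.clsm_dir, "clsm")
    annot = resolve(config.annotations, "annotations.csv")

    chash = config.config_hash()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("config hash %s; writing to %s", chash, outdir)

    modalities: dict[str, pd.DataFrame] = {}
    if tens_dir and tens_dir.is_dir():
        per_specimen = stage_tensile(tens_dir, config)
        io.write_table(outdir / "tensile_specimens.csv", per_specimen, chash, index=False)
        modalities["tensile"] = aggregate_tensile(per_specimen)
        io.write_table(outdir / "tensile_products.csv", modalities["tensile"], chash, index=False)
    if dic_dir and dic_dir.is_dir():
        modalities["dic"] = stage_dic(dic_dir, config)
        io.write_table(outdir / "dic_products.csv", modalities["dic"], chash, index=False)
    if tomo_dir and tomo_dir.is_dir():
        per_tomo = stage_tomo(tomo_dir, config)
        io.write_table(outdir / "tomo_specimens.csv", per_tomo, chash, index=False)
        modalities["tomo"] = per_tomo.drop(columns=["replicate"])
    if clsm_dir and clsm_dir.is_dir():
        per_clsm = stage_clsm(clsm_dir, config)
        io.write_table(outdir / "clsm_images.csv", per_clsm, chash, index=False)
        modalities["clsm"] = per_clsm.drop(columns=["image"])
    if not modalities:
        raise UsageError("no modality inputs found")

    if annot and Path(annot).exists():
        metadata = pd.read_csv(annot)
    else:
        products = sorted(
            set().union(*[set(m["product"]) for m in modalities.values()])
        )
        metadata = pd.DataFrame({"product": products, "product_set": "all"})

    results = integrate(modalities, metadata, config)
    io.write_table(outdir / "feature_table.csv", results["feature_table"], chash)
    var = results["variance_combined"]
    io.write_table(
        outdir / "variance_combined.csv",
        pd.DataFrame(
            {"variance": var.variances, "flagged": var.variances.index.isin(var.flagged)}
        ),
        chash,
    )
    io.write_table(outdir / "pearson_combined.csv", results["pearson_combined"].r, chash)
    for label, res in results["per_set"].items():
        io.write_table(outdir / f"pearson_{label}.csv", res["pearson"].r, chash)
        v = res["variance"]
        io.write_table(
            outdir / f"variance_{label}.csv",
            pd.DataFrame({"variance": v.variances, "flagged": v.variances.index.isin(v.flagged)}),
            chash,
        )
    sel_rows = []
    for target, sel in results["selections"].items():
        for rank, feat in enumerate(sel.selected, start=1):
            sel_rows.append({"target": target, "rank": rank, "feature": feat})
    if sel_rows:
        io.write_table(outdir / "feature_selection.csv", pd.DataFrame(sel_rows), chash, index=False)
    return results
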