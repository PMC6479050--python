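"""Stage drivers wiring the library into file-in/file-out pipeline steps.

Each ``run_*`` function consumes the standard input formats, executes one
analysis stage and writes its result tables under an output directory;
``run_all`` chains simulate -> classify -> profile -> beta -> distance on a
single configuration. Everything is deterministic given the seed: rerunning
a stage on the same inputs reproduces its outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beta import (
    RPConfig,
    direct_targets,
    distance_comparison,
    group_genes,
    ks_activating_repressive,
    regulatory_potential,
)
from .core import GenomicInterval
from .io import (
    read_bedgraph,
    read_expression,
    read_gene_models,
    read_intervals,
    write_json,
    write_table,
)
from .peaks import (
    annotate_distribution,
    classification_frame,
    classify_peaks,
    width_stats,
)
from .profiles import (
    average_profile,
    binned_matrix,
    matrix_frame,
    proximal_distal_correlation,
    site_signal_change,
)
from .simulate import SimulationConfig, simulate_study, write_study

log = logging.getLogger("bindexpr")


def _metadata(outdir: Path, stage: str, params: dict, inputs: dict[str, str | Path]) -> None:
    """Run provenance: version, parameters, input content hashes."""
    hashes = {}
    for name, path in inputs.items():
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        hashes[name] = h.hexdigest()
    write_json(
        {"stage": stage, "version": __version__, "parameters": params, "input_sha256": hashes},
        outdir / "run_metadata.json",
    )


def run_simulate(config: SimulationConfig, outdir: str | Path, include_signal: bool = True):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config, include_signal=include_signal)
    write_study(study, outdir)
    log.info(
        "simulate: %d genes, %d focal + %d partner peaks on %d chromosomes",
        len(study.genes), len(study.focal_peaks), len(study.partner_peaks), config.n_chroms,
    )
    return study


def run_classify(
    focal_path: str | Path,
    partner_path: str | Path,
    genes_path: str | Path,
    outdir: str | Path,
    promoter_halfwidth: int = 1000,
    min_overlap: int = 1,
    peak_format: str = "narrowpeak",
):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    focal = read_intervals(focal_path, peak_format)
    partner = read_intervals(partner_path, peak_format)
    genes = read_gene_models(genes_path)
    classification = classify_peaks(focal, partner, min_overlap=min_overlap)
    frame = classification_frame(classification, focal, partner)
    write_table(frame, outdir / "classes.tsv")
    dist_rows = []
    for label, subset in (
        ("all_focal", focal),
        ("I", [focal[i] for i in classification.focal_indices("I")]),
        ("II", [focal[i] for i in classification.focal_indices("II")]),
        ("III", [partner[j] for j, c in enumerate(classification.partner_classes) if c == "III"]),
    ):
        dist = annotate_distribution(subset, genes, promoter_halfwidth)
        row = {"peak_set": label, "n": len(subset)}
        row.update(dist.fractions)
        dist_rows.append(row)
    write_table(pd.DataFrame(dist_rows), outdir / "distribution.tsv")
    write_table(width_stats(classification, focal, partner), outdir / "widths.tsv")
    counts = classification.counts()
    log.info(
        "classify: Class I %d, Class II %d, Class III %d (min_overlap=%d)",
        counts["I"], counts["II"], counts["III"], min_overlap,
    )
    _metadata(
        outdir,
        "classify",
        {"promoter_halfwidth": promoter_halfwidth, "min_overlap": min_overlap},
        {"focal": focal_path, "partner": partner_path, "genes": genes_path},
    )
    return classification


def load_classes(classes_path: str | Path, select: str = "all"):
    """Reload peaks from a classes.tsv, optionally filtered by class.

    ``select`` is ``all`` (focal peaks), ``class:I``, ``class:II`` (focal
    subsets) or ``class:III`` (unshared partner peaks).
    """
    df = pd.read_csv(classes_path, sep="\t", dtype={"peak": str, "partners": str})
    if select == "all":
        sub = df[df["role"] == "focal"]
    elif select.startswith("class:"):
        wanted = select.split(":", 1)[1]
        role = "partner" if wanted == "III" else "focal"
        sub = df[(df["role"] == role) & (df["class"] == wanted)]
    else:
        raise ValueError(f"unknown selection {select!r}")
    peaks = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.peak)
        for r in sub.itertuples()
    ]
    labels = sub["class"].tolist()
    return peaks, labels


def run_profile(
    track_a_path: str | Path,
    track_b_path: str | Path,
    classes_path: str | Path,
    genes_path: str | Path,
    expression_path: str | Path,
    outdir: str | Path,
    flank: int = 5000,
    bin_size: int = 50,
    site_window: int = 1000,
    pseudocount: float = 1.0,
    proximal_cutoff: int = 2000,
    method: str = "spearman",
):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    track_a = read_bedgraph(track_a_path)
    track_b = read_bedgraph(track_b_path)
    genes = read_gene_models(genes_path)
    expression = read_expression(expression_path)
    peaks, labels = load_classes(classes_path, "all")
    matrix = binned_matrix(track_a, peaks, flank=flank, bin_size=bin_size, track_id="condition_a")
    matrix.row_labels = labels
    write_table(matrix_frame(matrix), outdir / "matrix.tsv")
    profiles = average_profile(matrix)
    prof_df = pd.DataFrame(profiles)
    prof_df.insert(0, "bin_start", matrix.bin_starts())
    write_table(prof_df, outdir / "profiles.tsv")
    changes = site_signal_change(
        track_a, track_b, peaks, window=site_window, pseudocount=pseudocount, genes=genes
    )
    write_table(changes, outdir / "site_changes.tsv")
    corr = proximal_distal_correlation(
        changes, expression, proximal_cutoff=proximal_cutoff, method=method
    )
    corr_out = {k: v for k, v in corr.items() if k != "per_site"}
    write_json(corr_out, outdir / "correlation.json")
    log.info(
        "profile: %d sites; proximal rho=%.3f (n=%d), distal rho=%.3f (n=%d)",
        len(peaks),
        corr["proximal"]["rho"], corr["proximal"]["n"],
        corr["distal"]["rho"], corr["distal"]["n"],
    )
    _metadata(
        outdir,
        "profile",
        {
            "flank": flank, "bin": bin_size, "site_window": site_window,
            "pseudocount": pseudocount, "proximal_cutoff": proximal_cutoff, "method": method,
        },
        {
            "track_a": track_a_path, "track_b": track_b_path,
            "classes": classes_path, "genes": genes_path, "expression": expression_path,
        },
    )
    return corr


def run_beta(
    classes_path: str | Path,
    genes_path: str | Path,
    expression_path: str | Path,
    outdir: str | Path,
    select: str = "all",
    window: int = 100_000,
    da: int = 500,
    offset: float = 0.5,
    scale: float = 4.0,
    static_p_floor: float = 0.1,
    min_abs_lfc: float = 0.0,
):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = RPConfig(window=window, offset=offset, scale=scale, da=da)
    genes = read_gene_models(genes_path)
    expression = read_expression(expression_path)
    peaks, _ = load_classes(classes_path, select)
    rp = regulatory_potential(peaks, genes, cfg)
    write_table(rp.reset_index(), outdir / "rp.tsv")
    groups = group_genes(expression, cfg, static_p_floor=static_p_floor, min_abs_lfc=min_abs_lfc)
    groups_df = pd.DataFrame(
        [(g, grp) for grp, genes_ in (("up", groups.up), ("down", groups.down), ("static", groups.static)) for g in genes_],
        columns=["gene_id", "group"],
    )
    write_table(groups_df, outdir / "groups.tsv")
    result = ks_activating_repressive(rp, groups, label=select)
    write_json({"selection": select, "groups": result.stats}, outdir / "beta_result.json")
    write_table(result.curves, outdir / "curves.tsv")
    targets = direct_targets(rp, groups, expression)
    write_table(targets["up"], outdir / "targets_up.tsv")
    write_table(targets["down"], outdir / "targets_down.tsv")
    log.info(
        "beta[%s]: up KS p=%.3g (n=%d), down KS p=%.3g (n=%d); %d up / %d down direct targets",
        select,
        result.stats["up"]["p"], result.stats["up"]["n"],
        result.stats["down"]["p"], result.stats["down"]["n"],
        len(targets["up"]), len(targets["down"]),
    )
    _metadata(
        outdir,
        "beta",
        {
            "select": select, "window": window, "da": da, "offset": offset,
            "scale": scale, "static_p_floor": static_p_floor, "min_abs_lfc": min_abs_lfc,
        },
        {"classes": classes_path, "genes": genes_path, "expression": expression_path},
    )
    return result, targets


def run_distance(
    classes_path: str | Path,
    genes_path: str | Path,
    expression_path: str | Path,
    outdir: str | Path,
    select: str = "all",
    da: int = 500,
    static_p_floor: float = 0.1,
):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = read_gene_models(genes_path)
    expression = read_expression(expression_path)
    peaks, _ = load_classes(classes_path, select)
    groups = group_genes(expression, RPConfig(da=da), static_p_floor=static_p_floor)
    table = distance_comparison(peaks, genes, groups)
    write_table(table, outdir / "distances.tsv")
    med = {r["group"]: r["median"] for _, r in table.iterrows()}
    log.info(
        "distance[%s]: median nearest-peak distance up=%.0f down=%.0f static=%.0f",
        select, med.get("up", np.nan), med.get("down", np.nan), med.get("static", np.nan),
    )
    _metadata(
        outdir,
        "distance",
        {"select": select, "da": da, "static_p_floor": static_p_floor},
        {"classes": classes_path, "genes": genes_path, "expression": expression_path},
    )
    return table


def run_all(config: SimulationConfig, outdir: str | Path, stage_params: dict | None = None):
    """Chain all stages on one simulated study under ``outdir``.

    ``stage_params`` may carry per-stage keyword overrides under the keys
    ``classify``, ``profile``, ``beta`` and ``distance``.
    """
    outdir = Path(outdir)
    stage_params = stage_params or {}
    sim_dir = outdir / "sim"
    run_simulate(config, sim_dir)
    mark = config.mark
    run_classify(
        sim_dir / "focal.narrowPeak",
        sim_dir / "partner.narrowPeak",
        sim_dir / "genes.refflat",
        outdir / "classify",
        **stage_params.get("classify", {}),
    )
    classes = outdir / "classify" / "classes.tsv"
    run_profile(
        sim_dir / f"{mark}.wt.bedGraph",
        sim_dir / f"{mark}.ko.bedGraph",
        classes,
        sim_dir / "genes.refflat",
        sim_dir / "expression.tsv",
        outdir / "profile",
        **stage_params.get("profile", {}),
    )
    beta_params = dict(stage_params.get("beta", {}))
    selections = beta_params.pop("selections", ["all", "class:I", "class:II"])
    for select in selections:
        run_beta(
            classes,
            sim_dir / "genes.refflat",
            sim_dir / "expression.tsv",
            outdir / "beta" / select.replace(":", "_"),
            select=select,
            **beta_params,
        )
    # the distance stage shares the beta gene-group definition unless overridden
    distance_params = {
        k: beta_params[k] for k in ("da", "static_p_floor") if k in beta_params
    }
    distance_params.update(stage_params.get("distance", {}))
    run_distance(
        classes,
        sim_dir / "genes.refflat",
        sim_dir / "expression.tsv",
        outdir / "distance",
        **distance_params,
    )
    write_json(
        {"config": dataclasses.asdict(config), "stages": sorted(stage_params)},
        outdir / "run_metadata.json",
    )
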