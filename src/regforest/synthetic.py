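"""Seeded generators for every pipeline stage, with planted ground truth.

Three scenario families:

* a two-layer interactome (preferential-attachment PPI graph plus TF
  regulons of heterogeneous size) with matched differential-expression
  tables in which one planted regulator is up-regulated early and most of
  its regulon up-regulated late over a null background;
* small prize-collecting Steiner instances for oracle testing;
* synthetic confocal z-stacks of ellipsoidal nuclei with per-nucleus
  marker intensities, Gaussian blur and additive noise, plus a ground-truth
  table.

Every generator is a pure function of its parameters and seed: the same
seed reproduces byte-identical outputs.  A single scenario seed fans out to
per-generator child seeds via ``numpy.random.SeedSequence`` so the stages
can be tested independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from . import pcst
from .imaging import ZStack
from .interactome import (Interactome, assemble_interactome, load_ppi,
                          load_regulons)

DEFAULT_LFC_EARLY_PLANTED = 3.0
DEFAULT_REGULON_UP_FRACTION = 0.9
DEFAULT_LFC_LATE_TARGETS = 4.0
DEFAULT_N_DECOYS = 3
DEFAULT_BACKGROUND_SD = 0.3
DECOY_UP_FRACTION = 0.2
#: decoy early log2FC range; fixed so the planted effect size can sweep
#: through it when recovery degradation is probed
DECOY_LFC_RANGE = (0.5, 1.5)
SIGNIFICANT_PADJ = 1e-6


def _rng(seed, *spawn_key) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(seed, spawn_key=list(spawn_key))))


# ---------------------------------------------------------------------------
# interactome

def gen_interactome(n_proteins: int = 100, n_tfs: int = 8,
                    mean_ppi_degree: float = 4.0,
                    regulon_size_range: tuple = (5, 20),
                    seed: int = 0) -> dict[str, pd.DataFrame]:
    """Synthetic PPI + regulon tables in the interactome TSV dialects.

    PPI edges come from a preferential-attachment generator (confidences
    uniform on (0.4, 1.0)); the first ``n_tfs`` proteins are TFs, each
    drawing a regulon size uniformly from ``regulon_size_range`` and
    sampling targets from a shared rna-layer gene pool (so regulons
    overlap).  Returns ``{"ppi": ..., "regulons": ..., "truth": ...}``.
    """
    if n_tfs > n_proteins:
        raise ValueError("n_tfs cannot exceed n_proteins")
    if n_proteins < 2 or n_tfs < 0 or mean_ppi_degree <= 0:
        raise ValueError("infeasible sizes")
    lo, hi = regulon_size_range
    if lo < 1 or hi < lo:
        raise ValueError("bad regulon_size_range")

    rng = _rng(seed, 1)
    proteins = [f"Prot{i:04d}" for i in range(n_proteins)]
    tfs = [f"Tf{i:02d}" for i in range(n_tfs)]
    proteins[:n_tfs] = tfs

    # preferential attachment: node i attaches m edges to earlier nodes,
    # weighted by current degree + 1
    m = max(1, int(round(mean_ppi_degree / 2)))
    deg = np.zeros(n_proteins)
    edges = set()
    order = rng.permutation(n_proteins)  # attachment order decoupled from TF ids
    for step in range(1, n_proteins):
        i = order[step]
        earlier = order[:step]
        w = deg[earlier] + 1.0
        k = min(m, step)
        picks = rng.choice(earlier, size=k, replace=False, p=w / w.sum())
        for j in picks:
            a, b = sorted((int(i), int(j)))
            if (a, b) not in edges:
                edges.add((a, b))
                deg[a] += 1
                deg[b] += 1
    rows = []
    for (a, b) in sorted(edges):
        conf = rng.uniform(0.4, 1.0)
        rows.append({"protein1": proteins[a], "protein2": proteins[b],
                     "combined_score": int(round(conf * 1000))})
    ppi = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])

    pool = [f"Targ{i:04d}" for i in range(max(hi * 3, n_proteins))]
    reg_rows = []
    regulons = {}
    for tf in tfs:
        size = int(rng.integers(lo, hi + 1))
        targets = sorted(rng.choice(pool, size=size, replace=False).tolist())
        regulons[tf] = targets
        for t in targets:
            reg_rows.append({"tf": tf, "target": t, "source": "synthetic"})
    reg = pd.DataFrame(reg_rows, columns=["tf", "target", "source"])

    truth = {"tfs": tfs, "regulons": regulons, "n_proteins": n_proteins,
             "seed": int(seed)}
    return {"ppi": ppi, "regulons": reg, "truth": truth}


def tables_to_interactome(tables: dict) -> Interactome:
    """Assemble the generated tables with the default cost rules."""
    return assemble_interactome(
        load_ppi(tables["ppi"], score_scale="thousand"),
        load_regulons(tables["regulons"]))


# ---------------------------------------------------------------------------
# planted DE tables

@dataclass
class PlantedScenario:
    """Interactome + DE tables + ground truth for one planted-regulator run."""

    tables: dict
    de_early: pd.DataFrame
    de_late: pd.DataFrame
    truth: dict = field(default_factory=dict)
    seed: int = 0


def gen_planted_de(tables: dict, planted_tf: str,
                   lfc_early_planted: float = DEFAULT_LFC_EARLY_PLANTED,
                   regulon_up_fraction: float = DEFAULT_REGULON_UP_FRACTION,
                   lfc_late_targets: float = DEFAULT_LFC_LATE_TARGETS,
                   n_decoys: int = DEFAULT_N_DECOYS,
                   background_sd: float = DEFAULT_BACKGROUND_SD,
                   seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """DE tables with a planted early-up regulator whose regulon is late-up.

    The planted TF gets ``log2fc = lfc_early_planted`` with padj 1e-6 in the
    early contrast; ``regulon_up_fraction`` of its regulon gets
    ``lfc_late_targets`` (with small jitter) and padj 1e-6 in the late
    contrast.  Decoy TFs get log2fc drawn from U(0.5, 1.5) and only a small
    fraction (0.2) of their regulons up-regulated late.  All remaining genes
    are null background: log2fc ~ N(0, background_sd), padj ~ U(0, 1).

    Returns (de_early, de_late, truth).
    """
    truth_in = tables["truth"]
    regulons = truth_in["regulons"]
    if planted_tf not in regulons or not regulons[planted_tf]:
        raise ValueError(f"{planted_tf!r} is not a TF with a regulon")
    rng = _rng(seed, 2)

    tfs = list(truth_in["tfs"])
    other_tfs = [t for t in tfs if t != planted_tf]
    decoys = other_tfs[:n_decoys]

    # early contrast: protein-layer genes
    ppi = tables["ppi"]
    protein_genes = sorted(set(ppi["protein1"]) | set(ppi["protein2"]) | set(tfs))
    early_rows = []
    for g in protein_genes:
        if g == planted_tf:
            lfc, padj = lfc_early_planted, SIGNIFICANT_PADJ
        elif g in decoys:
            lfc = float(rng.uniform(*DECOY_LFC_RANGE))
            padj = 1e-4
        else:
            lfc = float(rng.normal(0.0, background_sd))
            padj = float(rng.uniform(0.0, 1.0))
        early_rows.append({"gene": g, "log2FoldChange": lfc, "padj": padj})
    de_early = pd.DataFrame(early_rows, columns=["gene", "log2FoldChange", "padj"])

    # late contrast: rna-layer genes (the regulon target pool)
    target_genes = sorted({t for regs in regulons.values() for t in regs})
    planted_regulon = list(regulons[planted_tf])
    n_up = int(round(regulon_up_fraction * len(planted_regulon)))
    planted_up = set(planted_regulon[:n_up])
    decoy_up = set()
    for d in decoys:
        reg = [t for t in regulons[d] if t not in planted_up]
        k = int(round(DECOY_UP_FRACTION * len(reg)))
        decoy_up |= set(reg[:k])
    late_rows = []
    for g in target_genes:
        if g in planted_up:
            lfc = float(lfc_late_targets + rng.normal(0.0, 0.2))
            padj = SIGNIFICANT_PADJ
        elif g in decoy_up:
            lfc = float(max(0.5, lfc_late_targets / 2 + rng.normal(0.0, 0.2)))
            padj = SIGNIFICANT_PADJ
        else:
            lfc = float(rng.normal(0.0, background_sd))
            padj = float(rng.uniform(0.0, 1.0))
        late_rows.append({"gene": g, "log2FoldChange": lfc, "padj": padj})
    de_late = pd.DataFrame(late_rows, columns=["gene", "log2FoldChange", "padj"])

    truth = {
        "planted_tf": planted_tf,
        "planted_regulon": planted_regulon,
        "planted_up_targets": sorted(planted_up),
        "decoys": decoys,
        "seed": int(seed),
    }
    return de_early, de_late, truth


def gen_planted_scenario(n_proteins: int = 100, n_tfs: int = 8,
                         mean_ppi_degree: float = 4.0,
                         regulon_size_range: tuple = (5, 20),
                         seed: int = 0, **de_kwargs) -> PlantedScenario:
    """Interactome plus matched DE tables; the planted TF is chosen by seed."""
    tables = gen_interactome(n_proteins=n_proteins, n_tfs=n_tfs,
                             mean_ppi_degree=mean_ppi_degree,
                             regulon_size_range=regulon_size_range, seed=seed)
    rng = _rng(seed, 3)
    tfs = tables["truth"]["tfs"]
    planted = tfs[int(rng.integers(len(tfs)))]
    de_early, de_late, truth = gen_planted_de(tables, planted, seed=seed, **de_kwargs)
    truth["interactome"] = tables["truth"]
    return PlantedScenario(tables=tables, de_early=de_early, de_late=de_late,
                           truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# small PCST instances

def gen_small_pcst_instance(n_nodes: int = 8, topology: str = "random",
                            seed: int = 0,
                            omega: float = pcst.DEFAULT_OMEGA) -> pcst.PCSTInstance:
    """Small seeded instance for the exact oracle (hard cap: 12 nodes).

    Costs ~ U(0.1, 2); half the nodes have prize 0, the rest ~ U(0, 5).
    Topologies: ``path``, ``star``, or ``random`` (a random tree plus a few
    extra edges).
    """
    if n_nodes > 12:
        raise ValueError("n_nodes > 12 exceeds the oracle budget")
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = _rng(seed, 4)
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    pairs = []
    if topology == "path":
        pairs = [(i, i + 1) for i in range(n_nodes - 1)]
    elif topology == "star":
        pairs = [(0, i) for i in range(1, n_nodes)]
    elif topology == "random":
        for i in range(1, n_nodes):
            pairs.append((int(rng.integers(i)), i))
        n_extra = int(rng.integers(0, n_nodes))
        for _ in range(n_extra):
            a, b = rng.choice(n_nodes, size=2, replace=False)
            a, b = int(min(a, b)), int(max(a, b))
            if (a, b) not in pairs:
                pairs.append((a, b))
    else:
        raise ValueError(f"unknown topology {topology!r}")
    edges = {}
    for (a, b) in pairs:
        edges[(nodes[a], nodes[b])] = float(rng.uniform(0.1, 2.0))
    prized = rng.permutation(n_nodes)[: n_nodes - n_nodes // 2]
    prizes = {nodes[int(i)]: float(rng.uniform(0.0, 5.0)) for i in prized}
    return pcst.PCSTInstance(nodes=nodes, edges=edges, prizes=prizes, omega=omega)


# ---------------------------------------------------------------------------
# confocal stacks

@dataclass
class StackTruth:
    """Ground truth for a generated stack: one row per nucleus."""

    table: pd.DataFrame  # center_{x,y,z}_um, semi_{x,y,z}_um, true_<channel>
    shape_um: tuple
    seed: int


def gen_confocal_stack(n_nuclei: int = 20,
                       radius_range_um: tuple = (3.5, 5.0),
                       min_center_dist_um: float = 15.0,
                       channel_intensity_map: dict | None = None,
                       noise_sd: float = 10.0,
                       pixel_size_xy: float = 0.3,
                       z_step: float = 1.0,
                       shape_um: tuple = (24.0, 96.0, 96.0),
                       dapi_level: float = 300.0,
                       blur_sigma_um: float = 0.5,
                       seed: int = 0) -> tuple[ZStack, StackTruth]:
    """Ellipsoidal nuclei painted into a blurred, noisy multi-channel stack.

    Nuclei centers are placed by rejection sampling at pairwise distance
    >= ``min_center_dist_um`` (error after bounded retries).  The DAPI
    channel paints nucleus foreground at ``dapi_level``; each marker channel
    in ``channel_intensity_map`` paints per-nucleus true means drawn
    uniformly from its (lo, hi) range.  The stack is Gaussian-blurred
    (sigma ~ ``blur_sigma_um``) and additive Gaussian noise (``noise_sd``)
    is applied, clipped at 0.
    """
    if channel_intensity_map is None:
        channel_intensity_map = {"marker": (100.0, 500.0)}
    if pixel_size_xy <= 0 or z_step <= 0:
        raise ValueError("voxel geometry must be positive")
    rng = _rng(seed, 5)
    zdim, ydim, xdim = shape_um
    rmax = radius_range_um[1]
    margin_xy, margin_z = rmax + 1.0, rmax * 0.8 + 1.0

    centers: list[np.ndarray] = []
    for _restart in range(20):
        centers = []
        attempts = 0
        while len(centers) < n_nuclei and attempts < 400 * n_nuclei:
            attempts += 1
            c = np.array([rng.uniform(margin_z, zdim - margin_z),
                          rng.uniform(margin_xy, ydim - margin_xy),
                          rng.uniform(margin_xy, xdim - margin_xy)])
            if all(np.linalg.norm(c - p) >= min_center_dist_um for p in centers):
                centers.append(c)
        if len(centers) == n_nuclei:
            break
    if len(centers) < n_nuclei:
        raise RuntimeError(
            f"could not place {n_nuclei} nuclei at {min_center_dist_um} um "
            "separation; use fewer nuclei or a larger stack")

    radii = rng.uniform(radius_range_um[0], radius_range_um[1], size=n_nuclei)
    channels = ["dapi"] + sorted(channel_intensity_map)
    true_means = {ch: rng.uniform(lo, hi, size=n_nuclei)
                  for ch, (lo, hi) in sorted(channel_intensity_map.items())}

    nz = int(round(zdim / z_step))
    ny = int(round(ydim / pixel_size_xy))
    nx = int(round(xdim / pixel_size_xy))
    zz = (np.arange(nz) + 0.5) * z_step
    yy = (np.arange(ny) + 0.5) * pixel_size_xy
    xx = (np.arange(nx) + 0.5) * pixel_size_xy

    data = np.zeros((len(channels), nz, ny, nx), np.float32)
    rows = []
    for i, c in enumerate(centers):
        r_xy = radii[i]
        r_z = 0.8 * r_xy  # oblate: squashed along the optical axis
        z0, y0, x0 = c
        zsel = np.abs(zz - z0) <= r_z
        ysel = np.abs(yy - y0) <= r_xy
        xsel = np.abs(xx - x0) <= r_xy
        zi, yi, xi = np.nonzero(zsel)[0], np.nonzero(ysel)[0], np.nonzero(xsel)[0]
        dz = ((zz[zi] - z0) / r_z)[:, None, None]
        dy = ((yy[yi] - y0) / r_xy)[None, :, None]
        dx = ((xx[xi] - x0) / r_xy)[None, None, :]
        inside = dz ** 2 + dy ** 2 + dx ** 2 <= 1.0
        sub = np.ix_(zi, yi, xi)
        block = data[0][sub]
        block[inside] = dapi_level
        data[0][sub] = block
        for ci, ch in enumerate(channels[1:], start=1):
            block = data[ci][sub]
            block[inside] = true_means[ch][i]
            data[ci][sub] = block
        row = {"nucleus": i + 1, "center_x_um": x0, "center_y_um": y0,
               "center_z_um": z0, "semi_x_um": r_xy, "semi_y_um": r_xy,
               "semi_z_um": r_z,
               "volume_um3": 4.0 / 3.0 * np.pi * r_xy * r_xy * r_z,
               "true_dapi": dapi_level}
        for ch in channels[1:]:
            row[f"true_{ch}"] = float(true_means[ch][i])
        rows.append(row)

    sigma = (blur_sigma_um / z_step, blur_sigma_um / pixel_size_xy,
             blur_sigma_um / pixel_size_xy)
    for ci in range(len(channels)):
        data[ci] = ndi.gaussian_filter(data[ci], sigma=sigma)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)
        np.clip(data, 0.0, None, out=data)

    stack = ZStack(data=data, pixel_size_xy=pixel_size_xy, z_step=z_step,
                   channels=channels)
    truth = StackTruth(table=pd.DataFrame(rows), shape_um=tuple(shape_um),
                       seed=int(seed))
    return stack, truth


# ---------------------------------------------------------------------------
# file output for the CLI

def write_planted_scenario(scenario: PlantedScenario, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["ppi"] = outdir / "ppi.tsv"
    scenario.tables["ppi"].to_csv(paths["ppi"], sep="\t", index=False)
    paths["regulons"] = outdir / "regulons.tsv"
    scenario.tables["regulons"].to_csv(paths["regulons"], sep="\t", index=False)
    paths["de_early"] = outdir / "de_early.tsv"
    scenario.de_early.to_csv(paths["de_early"], sep="\t", index=False,
                             float_format="%.17g")
    paths["de_late"] = outdir / "de_late.tsv"
    scenario.de_late.to_csv(paths["de_late"], sep="\t", index=False,
                            float_format="%.17g")
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(scenario.truth, indent=2, sort_keys=True)
                              + "\n")
    return paths
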