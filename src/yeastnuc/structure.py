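"""Ensemble-level structural statistics of simulated nuclei.

Operates on :class:`~yeastnuc.simulate.Ensemble` objects (stacks of bead
coordinates in nm, nucleus-centred) and the bead chains of the matching
karyotype.  Implements the radial shell occupancy and per-gene
percent-peripheral summaries, nuclear-envelope and SPB displacement
tables, locus distance statistics, in-silico contact maps and the 2D
(axial, radial) localisation density maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .geometry import NuclearGeometry, classify_shell
from .karyotype import BeadChain, Karyotype
from .simulate import Ensemble

__all__ = [
    "ShellOccupancy",
    "ContactMap",
    "shell_occupancy",
    "gene_percent_peripheral",
    "gene_position_table",
    "locus_ne_displacement_10kb",
    "spb_distance_difference",
    "pair_distance_stats",
    "density_map_2d",
    "contact_map",
    "matrix_distance_correlation",
]


@dataclass
class ShellOccupancy:
    """Per-bead fractions of conformations spent in each radial shell."""

    central: np.ndarray
    middle: np.ndarray
    peripheral: np.ndarray
    n_conformations: int

    @property
    def percent_peripheral(self) -> np.ndarray:
        return 100.0 * self.peripheral


def shell_occupancy(
    ensemble: Ensemble, geometry: Optional[NuclearGeometry] = None
) -> ShellOccupancy:
    """Fraction of conformations each bead spends central/middle/peripheral.

    Beads found outside the nucleus (restraint tolerance overshoot) are
    counted as peripheral.
    """
    geometry = geometry or NuclearGeometry()
    P = ensemble.positions_array()
    if P.shape[0] == 0:
        raise ValueError("empty ensemble")
    codes = classify_shell(P, geometry.R_nuc)
    outside = codes == 3
    if outside.any():
        codes = np.where(outside, 2, codes)
    return ShellOccupancy(
        central=(codes == 0).mean(axis=0),
        middle=(codes == 1).mean(axis=0),
        peripheral=(codes == 2).mean(axis=0),
        n_conformations=P.shape[0],
    )


def _chain_offsets(chains: Sequence[BeadChain]) -> dict[str, int]:
    out, off = {}, 0
    for ch in chains:
        out[ch.chromosome] = off
        off += ch.n_beads
    return out


def gene_beads(
    chains: Sequence[BeadChain], genes: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Global bead indices overlapping each gene interval.

    ``genes`` needs columns ``gene``, ``chrom`` (source chromosome label),
    ``start``, ``end`` (bp, half-open, source coordinates).  A gene whose
    interval overlaps no surviving bead (deleted by a fusion junction) maps
    to an empty index array.
    """
    offsets = _chain_offsets(chains)
    out: dict[str, np.ndarray] = {}
    for row in genes.itertuples(index=False):
        hits = np.array([], dtype=np.int64)
        for ch in chains:
            idx = ch.beads_overlapping(row.chrom, int(row.start), int(row.end))
            if idx.size:
                hits = offsets[ch.chromosome] + idx
                break
        out[row.gene] = hits
    return out


def gene_percent_peripheral(
    occupancy: ShellOccupancy,
    chains: Sequence[BeadChain],
    genes: pd.DataFrame,
) -> pd.Series:
    """Per-gene % peripheral: unweighted mean over the gene's beads, x100.

    Genes with no surviving beads are returned as NaN (deleted during a
    fusion; excluded from downstream comparisons).
    """
    beads = gene_beads(chains, genes)
    vals = {
        g: (100.0 * float(occupancy.peripheral[idx].mean()) if idx.size else np.nan)
        for g, idx in beads.items()
    }
    return pd.Series(vals, name="percent_peripheral")


def gene_position_table(
    occ_wt: ShellOccupancy,
    chains_wt: Sequence[BeadChain],
    occ_strain: ShellOccupancy,
    chains_strain: Sequence[BeadChain],
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene positional comparison of a strain against wild type.

    Returns % peripheral in both karyotypes, the strain-minus-WT change in
    percentage points, the WT distance of the gene midpoint to the nearest
    chromosome end and to its centromere (kb), and a flag for genes whose
    chromosome lost its centromere in the fusion plan.  Genes deleted in
    the strain carry NaN and a ``deleted`` flag.
    """
    pp_wt = gene_percent_peripheral(occ_wt, chains_wt, genes)
    pp_st = gene_percent_peripheral(occ_strain, chains_strain, genes)

    wt_by_source = {ch.chromosome: ch for ch in chains_wt}
    cen_lost, d_tel, d_cen = {}, {}, {}
    strain_cen_sources = set()
    for ch in chains_strain:
        for i in np.flatnonzero(ch.is_centromere):
            strain_cen_sources.add(ch.source[i])
    for row in genes.itertuples(index=False):
        ch = wt_by_source.get(row.chrom)
        if ch is None:
            d_tel[row.gene] = np.nan
            d_cen[row.gene] = np.nan
            cen_lost[row.gene] = False
            continue
        mid = 0.5 * (row.start + row.end)
        L = ch.length_bp
        d_tel[row.gene] = min(mid, L - mid) / 1000.0
        cen_bp = float(ch.src_start[np.flatnonzero(ch.is_centromere)[0]])
        d_cen[row.gene] = abs(mid - cen_bp) / 1000.0
        cen_lost[row.gene] = row.chrom not in strain_cen_sources

    df = pd.DataFrame(
        {
            "percent_peripheral_wt": pp_wt,
            "percent_peripheral_strain": pp_st,
            "delta_percent_peripheral": pp_st - pp_wt,
            "dist_telomere_kb": pd.Series(d_tel),
            "dist_centromere_kb": pd.Series(d_cen),
            "cen_lost": pd.Series(cen_lost),
        }
    )
    df["deleted"] = df["percent_peripheral_strain"].isna()
    df.index.name = "gene"
    return df


def _ne_distance(P: np.ndarray, R_nuc: float) -> np.ndarray:
    """Distance of each bead centre to the nuclear envelope, nm."""
    return R_nuc - np.linalg.norm(P, axis=-1)


def locus_ne_displacement_10kb(
    ens_a: Ensemble,
    ens_b: Ensemble,
    chains: Sequence[BeadChain],
    geometry: Optional[NuclearGeometry] = None,
    beads_per_locus: int = 3,
) -> pd.DataFrame:
    """Mean NE distance per ~10-kb locus (3 beads) in two ensembles.

    Both ensembles must share the bead layout described by ``chains``.
    Loci are non-overlapping groups of ``beads_per_locus`` consecutive
    beads from each chain start; a trailing remainder forms a final short
    locus.  The ``displacement`` column is b minus a (positive = further
    from the envelope in ensemble b).
    """
    geometry = geometry or NuclearGeometry()
    da = _ne_distance(ens_a.positions_array(), geometry.R_nuc).mean(axis=0)
    db = _ne_distance(ens_b.positions_array(), geometry.R_nuc).mean(axis=0)
    rows = []
    off = 0
    for ch in chains:
        n = ch.n_beads
        for lo in range(0, n, beads_per_locus):
            hi = min(lo + beads_per_locus, n)
            sl = slice(off + lo, off + hi)
            rows.append(
                {
                    "chromosome": ch.chromosome,
                    "start_bp": int(ch.comp_start[lo]),
                    "end_bp": int(ch.comp_end[hi - 1]),
                    "ne_dist_a_nm": float(da[sl].mean()),
                    "ne_dist_b_nm": float(db[sl].mean()),
                }
            )
        off += n
    df = pd.DataFrame(rows)
    df["displacement_nm"] = df["ne_dist_b_nm"] - df["ne_dist_a_nm"]
    return df


def spb_distance_difference(
    ens_wt: Ensemble,
    ens_fc: Ensemble,
    geometry: Optional[NuclearGeometry] = None,
) -> np.ndarray:
    """Per-bead mean distance to the SPB, FC minus WT (nm).

    Positive values mean the bead sits further from the SPB in the fusion
    strain than in wild type.  Requires a shared bead layout.
    """
    geometry = geometry or NuclearGeometry()
    c = np.asarray(geometry.c_spb)
    d_wt = np.linalg.norm(ens_wt.positions_array() - c, axis=-1).mean(axis=0)
    d_fc = np.linalg.norm(ens_fc.positions_array() - c, axis=-1).mean(axis=0)
    return d_fc - d_wt


def pair_distance_stats(
    ensemble: Ensemble,
    beads_a: np.ndarray,
    beads_b: Optional[np.ndarray] = None,
    reference: Optional[str] = None,
    geometry: Optional[NuclearGeometry] = None,
) -> dict:
    """Distribution of a locus distance over the ensemble.

    A locus is a set of global bead indices; its per-conformation distance
    is the mean of the constitutive beads' distances.  With ``beads_b``
    the locus-locus distance is used; with ``reference`` "SPB" or "NE" the
    distance to that landmark.  Returns mean, SD and median in nm.
    """
    geometry = geometry or NuclearGeometry()
    P = ensemble.positions_array()
    A = P[:, np.asarray(beads_a, dtype=int)]
    if beads_b is not None:
        B = P[:, np.asarray(beads_b, dtype=int)]
        # mean over all bead pairs of the two loci
        d = np.linalg.norm(A[:, :, None, :] - B[:, None, :, :], axis=-1).mean(axis=(1, 2))
    elif reference == "SPB":
        d = np.linalg.norm(A - np.asarray(geometry.c_spb), axis=-1).mean(axis=1)
    elif reference == "NE":
        d = (geometry.R_nuc - np.linalg.norm(A, axis=-1)).mean(axis=1)
    else:
        raise ValueError("provide beads_b or reference='SPB'|'NE'")
    return {
        "mean_nm": float(d.mean()),
        "sd_nm": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        "median_nm": float(np.median(d)),
        "n": int(len(d)),
    }


def telomere_pair_median_distances(
    ensemble: Ensemble, chains: Sequence[BeadChain], max_pairs: Optional[int] = None
) -> pd.DataFrame:
    """Median distance between telomere (terminal-bead) pairs over the ensemble."""
    offsets = _chain_offsets(chains)
    tels = []
    for ch in chains:
        o = offsets[ch.chromosome]
        tels.append((f"{ch.chromosome}-L", o))
        tels.append((f"{ch.chromosome}-R", o + ch.n_beads - 1))
    P = ensemble.positions_array()
    rows = []
    for i in range(len(tels)):
        for j in range(i + 1, len(tels)):
            (na, a), (nb, b) = tels[i], tels[j]
            d = np.linalg.norm(P[:, a] - P[:, b], axis=-1)
            rows.append({"telomere_a": na, "telomere_b": nb, "median_nm": float(np.median(d))})
            if max_pairs is not None and len(rows) >= max_pairs:
                return pd.DataFrame(rows)
    return pd.DataFrame(rows)


def density_map_2d(
    ensemble: Ensemble,
    bead_indices: Optional[np.ndarray] = None,
    grid_nm: float = 2000.0,
    pixel_nm: float = 10.0,
    blur_sigma_nm: float = 30.0,
) -> np.ndarray:
    """2D localisation probability density in (axial, radial) coordinates.

    Beads are projected to (a, rho) = (x, sqrt(y^2 + z^2)), accumulated on
    a square grid (``grid_nm`` on a side, ``pixel_nm`` cells, a in
    [-grid/2, grid/2], rho in [0, grid)), blurred with a Gaussian of
    ``blur_sigma_nm`` and normalised to a maximum of 1.

    Returns the (n_a, n_rho) array; index [i, j] is the cell at
    a = -grid/2 + i*pixel, rho = j*pixel.
    """
    P = ensemble.positions_array()
    if bead_indices is not None:
        P = P[:, np.asarray(bead_indices, dtype=int)]
    pts = P.reshape(-1, 3)
    a = pts[:, 0]
    rho = np.hypot(pts[:, 1], pts[:, 2])
    n = int(round(grid_nm / pixel_nm))
    H, _, _ = np.histogram2d(
        a, rho, bins=n, range=[[-grid_nm / 2, grid_nm / 2], [0.0, grid_nm]]
    )
    H = gaussian_filter(H, sigma=blur_sigma_nm / pixel_nm, mode="constant")
    m = H.max()
    return H / m if m > 0 else H


@dataclass
class ContactMap:
    """Genome-wide bin-pair contact frequencies from an ensemble."""

    matrix: np.ndarray
    bin_chrom: list[str]
    bin_start: np.ndarray  # chain coordinates, bp
    bin_end: np.ndarray
    cutoff_nm: float
    beads_per_bin: int

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self) -> str:
        hdr = "\t".join(
            f"{c}:{s}-{e}" for c, s, e in zip(self.bin_chrom, self.bin_start, self.bin_end)
        )
        body = "\n".join("\t".join(f"{v:.6g}" for v in row) for row in self.matrix)
        return hdr + "\n" + body + "\n"


def save_density_map_png(
    density: np.ndarray, path, grid_nm: float = 2000.0, cmap: str = "magma"
) -> None:
    """Render a 2D (axial, radial) density map to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    half = grid_nm / 2.0
    im = ax.imshow(
        density.T,
        origin="lower",
        extent=(-half, half, 0.0, grid_nm),
        cmap=cmap,
        aspect="equal",
    )
    ax.set_xlabel("axial position a (nm, SPB at left)")
    ax.set_ylabel("radial position rho (nm)")
    fig.colorbar(im, ax=ax, label="normalised density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def contact_map(
    ensemble: Ensemble,
    chains: Sequence[BeadChain],
    cutoff_nm: float = 120.0,
    beads_per_bin: int = 10,
    mode: str = "any",
) -> ContactMap:
    """In-silico contact map: bead pairs within ``cutoff_nm`` are contacts.

    Bins are ``beads_per_bin`` consecutive beads (10 beads = 32 kb).  In
    the default ``mode="any"`` the bin-pair value is the fraction of
    conformations with at least one contacting bead pair (bounded in
    [0, 1] like a contact probability); ``mode="count"`` accumulates raw
    contacting-pair counts averaged over conformations.
    """
    if mode not in ("any", "count"):
        raise ValueError("mode must be 'any' or 'count'")
    bead_bin = []
    bin_chrom: list[str] = []
    bin_start: list[int] = []
    bin_end: list[int] = []
    for ch in chains:
        for lo in range(0, ch.n_beads, beads_per_bin):
            hi = min(lo + beads_per_bin, ch.n_beads)
            bin_chrom.append(ch.chromosome)
            bin_start.append(int(ch.comp_start[lo]))
            bin_end.append(int(ch.comp_end[hi - 1]))
            bead_bin.extend([len(bin_chrom) - 1] * (hi - lo))
    bead_bin = np.asarray(bead_bin, dtype=np.int64)
    nb = len(bin_chrom)
    P = ensemble.positions_array()
    M = np.zeros((nb, nb))
    for conf in P:
        tree = cKDTree(conf)
        pairs = tree.query_pairs(cutoff_nm, output_type="ndarray")
        bi = bead_bin[pairs[:, 0]]
        bj = bead_bin[pairs[:, 1]]
        if mode == "any":
            hit = np.zeros((nb, nb), dtype=bool)
            hit[bi, bj] = True
            hit[bj, bi] = True
            np.fill_diagonal(hit, False)
            M += hit
        else:
            np.add.at(M, (bi, bj), 1.0)
            np.add.at(M, (bj, bi), 1.0)
    M /= len(P)
    if mode == "any":
        np.fill_diagonal(M, 1.0)
    return ContactMap(
        matrix=M,
        bin_chrom=bin_chrom,
        bin_start=np.asarray(bin_start),
        bin_end=np.asarray(bin_end),
        cutoff_nm=cutoff_nm,
        beads_per_bin=beads_per_bin,
    )


def matrix_distance_correlation(
    model_map: ContactMap, experimental: np.ndarray, experimental_chrom: Sequence[str]
) -> pd.DataFrame:
    """Spearman correlation of two matrices per intra-chromosomal genomic distance.

    ``experimental`` must use the same bin scheme as ``model_map`` (one
    row/column per bin, same chromosome assignment); the experimental
    matrix is an externally preprocessed interaction map.  Returns one row
    per genomic-distance stratum (in bins) plus an ``overall`` row pooling
    all strata.
    """
    E = np.asarray(experimental, dtype=float)
    if E.shape != model_map.matrix.shape or list(experimental_chrom) != model_map.bin_chrom:
        raise ValueError("experimental matrix does not match the model bin scheme")
    chrom = np.asarray(model_map.bin_chrom, dtype=object)
    n = model_map.n_bins
    ii, jj = np.triu_indices(n, k=1)
    same = chrom[ii] == chrom[jj]
    ii, jj = ii[same], jj[same]
    dist = jj - ii
    rows = []
    pooled_m, pooled_e = [], []
    for s in np.unique(dist):
        sel = dist == s
        m = model_map.matrix[ii[sel], jj[sel]]
        e = E[ii[sel], jj[sel]]
        pooled_m.append(m)
        pooled_e.append(e)
        if sel.sum() >= 3 and np.std(m) > 0 and np.std(e) > 0:
            rho = spearmanr(m, e).statistic
        else:
            rho = np.nan
        rows.append({"distance_bins": int(s), "n_pairs": int(sel.sum()), "spearman": rho})
    m_all = np.concatenate(pooled_m)
    e_all = np.concatenate(pooled_e)
    rows.append(
        {
            "distance_bins": -1,
            "n_pairs": int(len(m_all)),
            "spearman": spearmanr(m_all, e_all).statistic if len(m_all) >= 3 else np.nan,
        }
    )
    return pd.DataFrame(rows)
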