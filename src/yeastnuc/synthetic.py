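"""Synthetic inputs: mini-karyotypes, position stubs and expression tables.

Every analysis stage can be exercised without external downloads.  The
expression generator emulates the statistical structure the analyses
assume in real RNA-seq abundances:

* per-gene baseline levels, log-normal across genes;
* a subtelomeric repression gradient (expression suppressed within a
  decay length of the chromosome ends);
* a configurable periphery-expression coupling: a gene's expression
  changes by a fraction ``periphery_effect`` per percentage point
  decrease of its peripheral residency relative to wild type (the
  headline setting 0.01/pp makes a 25-pp decrease a x1.25 increase);
* replicate noise in log2 space, and optional Poisson counting noise.

Position stubs provide per-gene percent-peripheral profiles (decaying
from chromosome ends in wild type, with configurable displacement on
fused arms) so the expression statistics can be tested independently of
the polymer simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .karyotype import BP_PER_BEAD, Karyotype, simple_chromosome

__all__ = [
    "ExpressionGeneratorParams",
    "make_mini_karyotype",
    "make_position_stub",
    "simulate_expression",
]


@dataclass
class ExpressionGeneratorParams:
    """Knobs of the synthetic expression generator.

    ``periphery_effect`` is the fractional expression change per
    percentage point of peripheral-residency decrease (linear-fraction
    parametrisation); ``subtel_depth_log2`` and ``subtel_decay_kb`` shape
    the repression gradient at chromosome ends; ``replicate_noise_sd`` is
    the log2-space SD between replicates (the 0.25 default is a
    placeholder magnitude for typical RNA-seq replicate scatter).
    """

    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    periphery_effect: float = 0.01  # fraction per pp decrease
    subtel_depth_log2: float = 2.0
    subtel_decay_kb: float = 10.0
    replicate_noise_sd: float = 0.25
    counting_library_size: Optional[float] = None  # reads; None = no counting noise
    log_space_effect: bool = False  # alternative log2-linear coupling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.periphery_effect < 0:
            raise ValueError("periphery effect must be non-negative")
        if self.subtel_decay_kb <= 0:
            raise ValueError("subtelomeric decay length must be positive")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate noise SD must be non-negative")


def make_mini_karyotype(
    n_chroms: int,
    lengths_bp: Sequence[int],
    seed: int = 0,
    centromere_frac: float = 0.5,
    gene_spacing_bp: int = 3200,
    gene_length_bp: int = 1600,
) -> tuple[Karyotype, pd.DataFrame]:
    """A small karyotype with evenly tiled synthetic genes.

    Chromosomes are named ``c1..cN`` with centromeres at
    ``centromere_frac`` of their length; genes tile each chromosome every
    ``gene_spacing_bp``.  Deterministic given the inputs (``seed`` is
    recorded for provenance; the layout itself is deterministic).
    """
    if len(lengths_bp) != n_chroms:
        raise ValueError("need one length per chromosome")
    chroms = []
    genes = []
    for i, L in enumerate(lengths_bp):
        if L <= 0:
            raise ValueError("chromosome lengths must be positive")
        name = f"c{i + 1}"
        cen = max(1, min(L - 1, int(L * centromere_frac)))
        chroms.append(simple_chromosome(name, int(L), cen))
        for j, start in enumerate(range(0, int(L) - gene_length_bp, gene_spacing_bp)):
            genes.append(
                {
                    "gene": f"{name}g{j + 1}",
                    "chrom": name,
                    "start": start,
                    "end": start + gene_length_bp,
                }
            )
    karyotype = Karyotype(chromosomes=chroms, name=f"mini{n_chroms}")
    return karyotype, pd.DataFrame(genes)


def make_position_stub(
    genes: pd.DataFrame,
    karyotype: Karyotype,
    profile: str = "wt",
    seed: int = 0,
    fused_sources: Optional[Sequence[str]] = None,
    displacement_pp: float = 25.0,
    displacement_decay_kb: float = 30.0,
    base_pp: float = 25.0,
    subtel_amp_pp: float = 60.0,
    subtel_decay_kb: float = 20.0,
    noise_pp: float = 2.0,
) -> pd.DataFrame:
    """Per-gene percent-peripheral profiles without running the simulator.

    Wild-type residency decays from the chromosome ends inward:
    ``base + amp * exp(-d_tel / decay)`` plus seeded noise, clipped to
    [0, 100].  With ``profile="fused"`` genes on ``fused_sources``
    chromosomes are displaced toward the interior, most strongly near
    their former telomeres.  Returns the standard gene-position columns
    (WT and strain residency, delta in pp, distances in kb, flags).
    """
    if profile not in ("wt", "fused"):
        raise ValueError("profile must be 'wt' or 'fused'")
    rng = np.random.default_rng(seed)
    lengths = {c.name: c.length_bp for c in karyotype.chromosomes}
    cen_off = {c.name: c.centromere_offset_bp() for c in karyotype.chromosomes}
    fused = set(fused_sources or [])
    rows = []
    for row in genes.itertuples(index=False):
        L = lengths[row.chrom]
        mid = 0.5 * (row.start + row.end)
        d_tel = min(mid, L - mid) / 1000.0
        d_cen = abs(mid - cen_off[row.chrom]) / 1000.0
        p_wt = base_pp + subtel_amp_pp * np.exp(-d_tel / subtel_decay_kb)
        p_wt = float(np.clip(p_wt + rng.normal(0.0, noise_pp), 0.0, 100.0))
        if profile == "fused" and row.chrom in fused:
            drop = displacement_pp * np.exp(-d_tel / displacement_decay_kb)
            p_st = float(np.clip(p_wt - drop, 0.0, 100.0))
        else:
            p_st = p_wt
        rows.append(
            {
                "gene": row.gene,
                "chrom": row.chrom,
                "percent_peripheral_wt": p_wt,
                "percent_peripheral_strain": p_st,
                "delta_percent_peripheral": p_st - p_wt,
                "dist_telomere_kb": d_tel,
                "dist_centromere_kb": d_cen,
                "cen_lost": row.chrom in fused,
                "deleted": False,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def simulate_expression(
    pct_peripheral: pd.DataFrame,
    dist_telomere_kb: pd.Series,
    params: ExpressionGeneratorParams,
    replicates: int = 4,
    wt_strain: str = "WT",
    deleted: Optional[pd.DataFrame] = None,
) -> ExpressionTable:
    """Generate a TPM table from per-gene positional profiles.

    ``pct_peripheral`` is genes x strains (must include ``wt_strain``) of
    peripheral residency in percent; ``dist_telomere_kb`` the wild-type
    distance to the nearest chromosome end.  For gene g, strain s and
    replicate r,

        TPM = 2 ** (mu_g - depth * exp(-d_g / lambda)
                    + log2(1 + eff * (P_g,WT - P_g,s)) + eps_r)

    with mu_g the gene's baseline, eps_r ~ N(0, replicate_noise_sd); with
    ``log_space_effect`` the coupling term is ``eff_log2 * (P_WT - P_s)``
    directly in log2 units.  Optional Poisson counting noise thins each
    value at the configured library size.  Genes marked in ``deleted``
    (genes x strains boolean) are NaN for that strain.
    """
    if wt_strain not in pct_peripheral.columns:
        raise ValueError(f"pct_peripheral must include the {wt_strain!r} column")
    P = pct_peripheral.astype(float)
    if ((P < 0) | (P > 100)).any().any():
        raise ValueError("percent peripheral values must lie in [0, 100]")
    genes = P.index
    d_tel = dist_telomere_kb.loc[genes].astype(float).to_numpy()
    rng = np.random.default_rng(params.seed)
    mu = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, size=len(genes))
    mu = mu - params.subtel_depth_log2 * np.exp(-d_tel / params.subtel_decay_kb)

    cols: dict[str, np.ndarray] = {}
    meta = []
    p_wt = P[wt_strain].to_numpy()
    for strain in P.columns:
        shift_pp = p_wt - P[strain].to_numpy()
        if params.log_space_effect:
            effect = params.periphery_effect * shift_pp
        else:
            effect = np.log2(np.maximum(1e-12, 1.0 + params.periphery_effect * shift_pp))
        for rep in range(1, replicates + 1):
            eps = (
                rng.normal(0.0, params.replicate_noise_sd, size=len(genes))
                if params.replicate_noise_sd > 0
                else 0.0
            )
            tpm = np.power(2.0, mu + effect + eps)
            if params.counting_library_size:
                lam = tpm * params.counting_library_size / 1e6
                tpm = rng.poisson(lam) * 1e6 / params.counting_library_size
            if deleted is not None and strain in deleted.columns:
                tpm = np.where(deleted[strain].loc[genes].to_numpy(), np.nan, tpm)
            name = f"{strain}_{rep}"
            cols[name] = tpm
            meta.append({"sample": name, "strain": strain, "replicate": rep})
    values = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(meta).set_index("sample")
    return ExpressionTable(values=values, samples=samples)
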