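"""Pipeline orchestration: simulate -> structure -> expression from one config.

A run config (YAML or dict) selects strains, simulation scale and
analysis options; :func:`run_pipeline` executes the stages in dependency
order under an output root, writing a frozen copy of the resolved config
and per-stage JSON manifests keyed by a config hash.  Re-running with an
unchanged config skips completed stages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as ynio
from .expression import (
    baseline_expression,
    binned_group_analysis,
    count_significant_movers,
    log2_fold_change,
)
from .geometry import NuclearGeometry
from .karyotype import Karyotype, scaled_wild_type, strain_karyotype
from .simulate import ForceField, SimulationSchedule, run_ensemble
from .structure import gene_position_table, shell_occupancy
from .synthetic import (
    ExpressionGeneratorParams,
    make_mini_karyotype,
    make_position_stub,
    simulate_expression,
)

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "out_dir": "runs/default",
    "seed": 0,
    "mode": "synthetic",  # "synthetic" (position stubs) or "simulate"
    "strains": ["FC-synthetic"],
    "karyotype": {"kind": "mini", "n_chroms": 4, "length_bp": 100_000},
    "simulate": {
        "scale": 0.1,
        "replicates": 5,
        "prelim_tau": 60.0,
        "production_tau": 300.0,
        "sample_every_tau": 30.0,
        "telomere_eps": 4.5,
    },
    "expression": {
        "replicates": 4,
        "periphery_effect": 0.01,
        "replicate_noise_sd": 0.25,
    },
}


class RunConfig:
    """Resolved pipeline configuration with a stable content hash."""

    def __init__(self, data: Optional[dict] = None):
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        for k, v in (data or {}).items():
            if isinstance(v, dict) and isinstance(merged.get(k), dict):
                merged[k].update(v)
            else:
                merged[k] = v
        self.data = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()[:16]

    def __getitem__(self, key):
        return self.data[key]


def _stage_done(stage_dir: Path, cfg_hash: str) -> bool:
    m = stage_dir / "stage_manifest.json"
    if not m.exists():
        return False
    try:
        return json.loads(m.read_text()).get("config_hash") == cfg_hash
    except json.JSONDecodeError:
        return False


def _mark_done(stage_dir: Path, cfg_hash: str, extra: Optional[dict] = None) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "stage_manifest.json").write_text(
        json.dumps({"config_hash": cfg_hash, **(extra or {})}, indent=1, sort_keys=True)
    )


def _build_karyotype(cfg: RunConfig) -> tuple[Karyotype, pd.DataFrame]:
    kc = cfg["karyotype"]
    if kc["kind"] == "mini":
        return make_mini_karyotype(
            kc["n_chroms"], [kc["length_bp"]] * kc["n_chroms"], seed=cfg["seed"]
        )
    if kc["kind"] == "scaled-wt":
        k = scaled_wild_type(kc.get("scale", 0.1))
    else:
        k = strain_karyotype(kc.get("strain", "WT"))
    # tile synthetic genes over whatever karyotype was selected
    genes = []
    for c in k.chromosomes:
        for j, start in enumerate(range(0, c.length_bp - 1600, 6400)):
            genes.append(
                {"gene": f"{c.name}g{j + 1}", "chrom": c.name, "start": start, "end": start + 1600}
            )
    return k, pd.DataFrame(genes)


def run_pipeline(config: RunConfig | dict | str | Path) -> Path:
    """Execute the configured stages; returns the run directory.

    Stages: (1) inputs — karyotype + gene annotations; (2) positions —
    either polymer-simulation ensembles reduced to per-gene residency or
    synthetic position stubs; (3) expression — synthetic TPM table; (4)
    analysis — baseline, fold changes, binned trend and mover counts.
    Completed stages (matching config hash) are skipped on re-run.
    """
    if not isinstance(config, RunConfig):
        if isinstance(config, (str, Path)):
            config = RunConfig.from_yaml(config)
        else:
            config = RunConfig(config)
    cfg_hash = config.hash()
    root = Path(config["out_dir"])
    root.mkdir(parents=True, exist_ok=True)
    (root / "config.resolved.yaml").write_text(yaml.safe_dump(config.data, sort_keys=True))

    seed = int(config["seed"])
    karyotype, genes = _build_karyotype(config)
    genes_path = root / "genes.tsv"
    genes.to_csv(genes_path, sep="\t", index=False)

    # ---- positions stage ---------------------------------------------
    pos_dir = root / "positions"
    strains = list(config["strains"])
    if not _stage_done(pos_dir, cfg_hash):
        pos_dir.mkdir(parents=True, exist_ok=True)
        tables: dict[str, pd.DataFrame] = {}
        if config["mode"] == "simulate":
            sc = config["simulate"]
            geo = NuclearGeometry()
            ff = ForceField(telomere_eps=sc["telomere_eps"])
            sch = SimulationSchedule(
                prelim_duration=sc["prelim_tau"],
                production_duration=sc["production_tau"],
                sample_every=sc["sample_every_tau"],
                n_replicates=sc["replicates"],
            )
            ens_wt = run_ensemble(karyotype, geo, ff, sch, master_seed=seed)
            ynio.write_ensemble(ens_wt, pos_dir / "WT")
            chains = karyotype.build_chains()
            occ_wt = shell_occupancy(ens_wt, geo)
            for strain in strains:
                k_fc = strain_karyotype(strain) if strain.startswith("FC(") else karyotype
                ens_fc = run_ensemble(k_fc, geo, ff, sch, master_seed=seed + 1)
                ynio.write_ensemble(ens_fc, pos_dir / strain)
                tables[strain] = gene_position_table(
                    occ_wt, chains, shell_occupancy(ens_fc, geo), k_fc.build_chains(), genes
                )
        else:
            fused = [c.name for c in karyotype.chromosomes[:1]]
            for strain in strains:
                tables[strain] = make_position_stub(
                    genes, karyotype, profile="fused", seed=seed, fused_sources=fused
                )
        for strain, tbl in tables.items():
            tbl.to_csv(pos_dir / f"{strain}.positions.tsv", sep="\t")
        _mark_done(pos_dir, cfg_hash, {"strains": strains})
    tables = {
        s: pd.read_csv(pos_dir / f"{s}.positions.tsv", sep="\t", index_col=0) for s in strains
    }

    # ---- expression stage --------------------------------------------
    expr_dir = root / "expression"
    ec = config["expression"]
    if not _stage_done(expr_dir, cfg_hash):
        expr_dir.mkdir(parents=True, exist_ok=True)
        pct = pd.DataFrame(
            {"WT": tables[strains[0]]["percent_peripheral_wt"]}
            | {s: tables[s]["percent_peripheral_strain"] for s in strains}
        )
        params = ExpressionGeneratorParams(
            periphery_effect=ec["periphery_effect"],
            replicate_noise_sd=ec["replicate_noise_sd"],
            seed=seed + 17,
        )
        expr = simulate_expression(
            pct, tables[strains[0]]["dist_telomere_kb"], params, replicates=ec["replicates"]
        )
        (expr_dir / "expression.tsv").write_text(expr.to_tsv())
        _mark_done(expr_dir, cfg_hash)
    from .expression import ExpressionTable

    expr = ExpressionTable.from_tsv(expr_dir / "expression.tsv")

    # ---- analysis stage ----------------------------------------------
    ana_dir = root / "analysis"
    if not _stage_done(ana_dir, cfg_hash):
        ana_dir.mkdir(parents=True, exist_ok=True)
        delta = pd.DataFrame({s: tables[s]["delta_percent_peripheral"] for s in strains})
        base = baseline_expression(expr, delta)
        lfc = log2_fold_change(expr, base)
        lfc.to_csv(ana_dir / "log2fc.tsv", sep="\t")
        d0 = delta[strains[0]].reindex(lfc.index)
        summary, contrasts = binned_group_analysis(d0.to_numpy(), lfc[strains[0]].to_numpy())
        summary.to_csv(ana_dir / "binned_groups.tsv", sep="\t")
        contrasts.to_csv(ana_dir / "tukey_contrasts.tsv", sep="\t", index=False)
        movers = count_significant_movers(expr, delta)
        (ana_dir / "summary.json").write_text(
            json.dumps(
                {
                    "n_genes": int(len(lfc)),
                    "anova_F": summary.attrs.get("anova_F"),
                    "anova_p": summary.attrs.get("anova_p"),
                    "n_movers": movers["n_movers"],
                    "n_significant_movers": movers["n_significant"],
                },
                indent=1,
            )
        )
        _mark_done(ana_dir, cfg_hash)
    return root
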