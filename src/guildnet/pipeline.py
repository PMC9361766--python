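"""End-to-end orchestration: simulate -> filter -> sparcc -> guilds ->
networks -> signatures, with a single global seed fanned out per stage and
a manifest recording inputs, outputs, hashes and wall time."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .containers import CountTable, SampleMetadata
from .errors import GuildnetError
from .guilds import (divide_tree, guild_group_comparison, guild_network,
                     prevalence_filter, ward_tree, _correlation_distance,
                     guild_abundance)
from .containers import SymmetricMatrix
from .networks import compare_networks, cooccurrence_network, host_association
from .signatures import (PAIRS, bootstrap_confirm, classify_signatures,
                         differential_abundance, stable_species)
from .simulate import SimulationConfig, default_cohort_config, simulate
from .sparcc import sparcc
from .stats import anosim, bray_curtis, diversity_table, pcoa

__all__ = ["RunConfig", "validate_inputs", "run_all"]


@dataclass
class RunConfig:
    out_dir: str = "guildnet_out"
    counts_path: str | None = None            # None: simulate instead
    metadata_path: str | None = None
    seed: int = 0
    stages: tuple[str, ...] = ("diversity", "sparcc", "guilds", "network",
                               "signatures")
    simulation: SimulationConfig | None = None
    # stage parameters (defaults follow the documented pipeline)
    min_prevalence: float = 0.2
    min_rel_abundance: float = 0.0
    pseudocount: float = 0.5
    exclusion_threshold: float = 0.8
    n_perm: int = 9999
    alpha: float = 0.001
    edge_threshold: float = 0.70
    network_min_prevalence: float = 0.2
    network_min_rel_abundance: float = 0.001
    rho_threshold: float = 0.7
    q_threshold: float = 0.05
    n_boot: int = 1000
    subsample_size: int = 10
    ci_level: float = 0.90
    min_family_fraction: float = 0.5

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = data.pop("simulation", None)
        cfg = cls(**data)
        if sim is not None:
            if "group_sizes" in sim:
                sim["group_sizes"] = dict(sim["group_sizes"])
            if "loading_range" in sim:
                sim["loading_range"] = tuple(sim["loading_range"])
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        if self.simulation is not None:
            out["simulation"] = dataclasses.asdict(self.simulation)
            out["simulation"]["loading_range"] = list(
                self.simulation.loading_range)
        return out


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(ct: CountTable, metadata: SampleMetadata) -> list[str]:
    """Report every violation of the input contract (empty list = clean)."""
    violations = []
    missing = [s for s in ct.sample_ids if s not in metadata.sample_ids]
    if missing:
        violations.append(f"metadata missing samples: {missing[:5]}")
    extra = [s for s in metadata.sample_ids if s not in ct.sample_ids]
    if extra:
        violations.append(f"metadata lists unknown samples: {extra[:5]}")
    zero_samples = [s for s in ct.sample_ids if ct.counts[s].sum() == 0]
    if zero_samples:
        violations.append(f"samples with zero total count: {zero_samples[:5]}")
    zero_taxa = int((ct.counts.sum(axis=1) == 0).sum())
    if zero_taxa:
        violations.append(f"{zero_taxa} taxa observed in no sample")
    fam = metadata.family_ids
    groups = metadata.groups
    for family in sorted(set(fam.dropna())):
        members = fam.index[fam == family]
        per_group = groups[members].value_counts()
        if (per_group > 1).any():
            violations.append(
                f"family {family} has >1 sample in a group: "
                f"{per_group[per_group > 1].to_dict()}")
    return violations


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest.

    Any stage failure halts the run; the manifest written to out_dir records
    the failing stage and a machine-readable error entry.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "warnings": []}
    (out_dir / "run_config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True))

    def record(stage: str, outputs: list[Path], started: float,
               seed: int | None, info: dict | None = None):
        manifest["stages"].append({
            "stage": stage,
            "outputs": {p.name: _sha256(p) for p in outputs},
            "wall_time_s": round(time.monotonic() - started, 3),
            "seed": seed, "info": info or {}})

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _run_stages(config, out_dir, manifest, record)
        manifest["warnings"] = sorted({str(w.message) for w in caught})
    except GuildnetError as exc:
        manifest["error"] = {"stage": manifest.get("current_stage", "unknown"),
                             "type": type(exc).__name__, "message": str(exc)}
        _write_manifest(out_dir, manifest)
        raise
    manifest.pop("current_stage", None)
    _write_manifest(out_dir, manifest)
    return manifest


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))


def _run_stages(config: RunConfig, out_dir: Path, manifest: dict, record):
    # -- inputs --------------------------------------------------------------
    manifest["current_stage"] = "inputs"
    started = time.monotonic()
    if config.counts_path is not None:
        ct = gio.read_count_table(config.counts_path)
        metadata = gio.read_metadata(config.metadata_path)
        record("inputs", [], started, None,
               {"counts": str(config.counts_path)})
    else:
        sim_cfg = config.simulation or default_cohort_config()
        sim_cfg = sim_cfg.replace(seed=_stage_seed(config.seed, "simulate"))
        ct, metadata, truth = simulate(sim_cfg)
        gio.write_count_table(ct, out_dir / "counts.tsv")
        gio.write_metadata(metadata, out_dir / "metadata.tsv")
        truth.to_json(out_dir / "truth.json")
        record("simulate", [out_dir / "counts.tsv", out_dir / "metadata.tsv",
                            out_dir / "truth.json"], started, sim_cfg.seed)

    manifest["current_stage"] = "validate"
    violations = validate_inputs(ct, metadata)
    if violations:
        raise GuildnetError("input validation failed: " + "; ".join(violations))
    rel = ct.to_relative()

    # -- diversity -----------------------------------------------------------
    if "diversity" in config.stages:
        manifest["current_stage"] = "diversity"
        started = time.monotonic()
        div = diversity_table(ct.counts)
        div["group"] = metadata.groups.loc[div.index]
        div.to_csv(out_dir / "diversity.tsv", sep="\t")
        bc = bray_curtis(rel)
        gio.write_matrix(bc.to_dataframe(), out_dir / "bray_curtis.tsv")
        coords = pcoa(bc, k=2).coordinates
        coords.to_csv(out_dir / "pcoa.tsv", sep="\t", index_label="sample_id")
        res = anosim(bc, metadata.groups.loc[bc.ids], n_perm=999,
                     seed=_stage_seed(config.seed, "anosim"))
        pd.DataFrame([{"R": res.statistic, "p_value": res.p_value,
                       "n_permutations": res.n_permutations}]).to_csv(
            out_dir / "anosim.tsv", sep="\t", index=False)
        record("diversity", [out_dir / f for f in
                             ("diversity.tsv", "bray_curtis.tsv", "pcoa.tsv",
                              "anosim.tsv")], started, res.seed,
               {"anosim_R": res.statistic, "anosim_p": res.p_value})

    # -- sparcc + guilds -----------------------------------------------------
    partition = None
    rho = None
    if "sparcc" in config.stages or "guilds" in config.stages:
        manifest["current_stage"] = "sparcc"
        started = time.monotonic()
        filtered = prevalence_filter(ct, config.min_prevalence,
                                     config.min_rel_abundance)
        if filtered is None:
            raise GuildnetError("no taxa pass the prevalence filter")
        result = sparcc(filtered, pseudocount=config.pseudocount,
                        exclusion_threshold=config.exclusion_threshold)
        rho = result.rho
        gio.write_matrix(rho.to_dataframe(), out_dir / "sparcc_rho.tsv")
        record("sparcc", [out_dir / "sparcc_rho.tsv"], started, None,
               {"n_taxa": rho.n, "n_excluded_pairs": len(result.excluded_pairs),
                "converged": result.converged})

    if "guilds" in config.stages:
        manifest["current_stage"] = "guilds"
        started = time.monotonic()
        tree = ward_tree(rho)
        dist = SymmetricMatrix(rho.ids, _correlation_distance(rho.values),
                               "distance")
        seed = _stage_seed(config.seed, "guilds")
        partition = divide_tree(tree, dist, n_perm=config.n_perm,
                                alpha=config.alpha, seed=seed)
        partition.to_frame().to_csv(out_dir / "guild_assignment.tsv",
                                    sep="\t", index=False)
        guild_abundance(partition, rel).to_csv(out_dir / "guild_abundance.tsv",
                                               sep="\t")
        tests = guild_group_comparison(partition, rel, metadata,
                                       config.q_threshold)
        tests.to_csv(out_dir / "guild_tests.tsv", sep="\t")
        partition.division_log.to_csv(out_dir / "division_log.tsv",
                                      sep="\t", index=False)
        net = guild_network(rho, partition, rel, config.edge_threshold)
        gio.write_network(net, out_dir / "guild_network.graphml", "graphml")
        record("guilds", [out_dir / f for f in
                          ("guild_assignment.tsv", "guild_abundance.tsv",
                           "guild_tests.tsv", "division_log.tsv",
                           "guild_network.graphml")], started, seed,
               {"n_guilds": partition.n_guilds})

    # -- per-group networks --------------------------------------------------
    if "network" in config.stages:
        manifest["current_stage"] = "network"
        started = time.monotonic()
        nets = {}
        outputs = []
        for group in ("G1", "G2", "G3"):
            if len(metadata.samples_in_group(group)) < 5:
                continue
            net = cooccurrence_network(
                rel, metadata, group,
                min_prevalence=config.network_min_prevalence,
                min_rel_abundance=config.network_min_rel_abundance,
                rho_threshold=config.rho_threshold,
                q_threshold=config.q_threshold)
            nets[group] = net
            path = out_dir / f"network_{group}.tsv"
            gio.write_network(net, path, "edge_tsv")
            outputs.append(path)
        info: dict = {g: n.number_of_edges() for g, n in nets.items()}
        if len(nets) >= 2:
            comparison = compare_networks(nets)
            comparison.edge_counts().to_csv(out_dir / "network_overlap.tsv",
                                            sep="\t", header=True)
            comparison.centrality_table.to_csv(
                out_dir / "network_centrality.tsv", sep="\t", index=False)
            outputs += [out_dir / "network_overlap.tsv",
                        out_dir / "network_centrality.tsv"]
        if metadata.host_vars.shape[1] > 0:
            assoc = host_association(rel, metadata,
                                     q_threshold=config.q_threshold)
            assoc.to_csv(out_dir / "host_association.tsv", sep="\t",
                         index=False)
            outputs.append(out_dir / "host_association.tsv")
        record("network", outputs, started, None, info)

    # -- signatures ----------------------------------------------------------
    if "signatures" in config.stages:
        manifest["current_stage"] = "signatures"
        started = time.monotonic()
        diff = differential_abundance(rel, metadata, config.q_threshold)
        sigs = classify_signatures(diff, config.q_threshold)
        sigs.to_csv(out_dir / "signatures.tsv", sep="\t")
        seed = _stage_seed(config.seed, "bootstrap")
        boot_frames = []
        for i, pair in enumerate(PAIRS):
            label = f"{pair[0]}_{pair[1]}"
            taxa = list(diff.index[diff[f"sig_{label}"]])
            if not taxa:
                continue
            boot_frames.append(bootstrap_confirm(
                rel, metadata, taxa, pair, config.n_boot,
                config.subsample_size, config.ci_level, seed + i))
        boot = pd.concat(boot_frames) if boot_frames else pd.DataFrame(
            columns=["pair", "ci_low", "ci_high", "mean_diff", "confirmed"])
        boot.to_csv(out_dir / "bootstrap.tsv", sep="\t")
        outputs = [out_dir / "signatures.tsv", out_dir / "bootstrap.tsv"]
        info = {"n_confirmed": int(boot["confirmed"].sum())
                if len(boot) else 0}
        fam = metadata.family_ids
        if fam.notna().sum() > 0:
            stable = stable_species(rel, metadata,
                                    config.min_family_fraction,
                                    p_threshold=0.05)
            stable.to_csv(out_dir / "stable_species.tsv", sep="\t")
            outputs.append(out_dir / "stable_species.tsv")
            info["n_stable"] = int(stable["stable"].sum())
        record("signatures", outputs, started, seed, info)
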