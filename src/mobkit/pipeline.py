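"""Config-driven orchestration of the full analysis.

A run either ingests existing files (OTU table, tree, metadata, gas series)
or simulates them, then executes the stages in order:

    simulate/ingest → kinetics → diversity → assembly → network

Each stage writes its outputs before the next starts; a single manifest
(``manifest.json``) records the package version, per-stage seeds, parameters,
and SHA-256 checksums of every output, so two runs with the same config are
byte-identical and verifiably so.

Per-stage seeds are derived from the master seed by hashing the stage name
(CRC-32), so stages can be rerun independently with identical randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__, assembly, diversity, kinetics, network, synthetic_data
from .io_core import (
    FLOAT_FORMAT,
    OtuTable,
    align_table_tree,
    read_gas_csv,
    read_metadata,
    read_otu_table,
    read_tree_newick,
    write_gas_csv,
    write_metadata,
    write_otu_table,
    write_tree_newick,
)

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger("mobkit")


class ConfigError(ValueError):
    """Configuration file failed validation; the message lists every problem."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------

_SYNTHETIC_KEYS = {
    "n_otus": int,
    "n_samples_per_group": int,
    "depth": int,
    "regime": (str, dict),
    "selection_strength": (int, float),
    "drift_concentration": (int, float),
}
_INPUT_KEYS = {
    "otu_table": str,
    "orientation": str,
    "tree": str,
    "metadata": str,
    "gas": str,
}
_NETWORK_KEYS = {
    "abundance_quantile": (int, float),
    "occurrence_fraction": (int, float),
    "stars_threshold": (int, float),
    "n_subsamples": int,
    "pseudocount": (int, float),
}
_ROBUSTNESS_KEYS = {"n_repeats": int, "max_fraction": (int, float),
                    "step": (int, float)}
_TOP_KEYS = {
    "seed": int,
    "output_dir": str,
    "synthetic": dict,
    "inputs": dict,
    "rarefaction_depth": (int, type(None)),
    "n_null": int,
    "n_permutations": int,
    "abundance_weighted": bool,
    "network": dict,
    "robustness": dict,
}


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    output_dir: str = "mobkit_run"
    synthetic: dict | None = None
    inputs: dict | None = None
    rarefaction_depth: int | None = None
    n_null: int = 999
    n_permutations: int = 999
    abundance_weighted: bool = True
    network: dict = field(default_factory=dict)
    robustness: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError(
                "exactly one of 'synthetic' and 'inputs' must be present"
            )


def _check_keys(section: dict, allowed: dict, where: str, errors: list) -> None:
    for key, value in section.items():
        if key not in allowed:
            errors.append(f"{where}: unknown key {key!r}")
            continue
        expected = allowed[key]
        if not isinstance(value, expected):
            errors.append(
                f"{where}.{key}: expected {expected}, got {type(value).__name__}"
            )


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and schema-check a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    errors: list[str] = []
    _check_keys(raw, _TOP_KEYS, "config", errors)
    if "synthetic" in raw and isinstance(raw["synthetic"], dict):
        _check_keys(raw["synthetic"], _SYNTHETIC_KEYS, "synthetic", errors)
    if "inputs" in raw and isinstance(raw["inputs"], dict):
        _check_keys(raw["inputs"], _INPUT_KEYS, "inputs", errors)
    if "network" in raw and isinstance(raw["network"], dict):
        _check_keys(raw["network"], _NETWORK_KEYS, "network", errors)
        st = raw["network"].get("stars_threshold")
        if st is not None and not (0 < st < 1):
            errors.append("network.stars_threshold must be in (0, 1)")
    if "robustness" in raw and isinstance(raw["robustness"], dict):
        _check_keys(raw["robustness"], _ROBUSTNESS_KEYS, "robustness", errors)
    if "synthetic" not in raw and "inputs" not in raw:
        raw["synthetic"] = {}
    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    return (zlib.crc32(f"{stage}:{master_seed}".encode()) ^ master_seed) % (2**31)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    file_handler = logging.FileHandler(out / "run.log", mode="w")
    fmt = logging.Formatter("%(asctime)s %(name)s %(message)s")
    for h in (handler, file_handler):
        h.setFormatter(fmt)
        logger.addHandler(h)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "mobkit_version": __version__,
        "seed": config.seed,
        "parameters": {
            "rarefaction_depth": config.rarefaction_depth,
            "n_null": config.n_null,
            "n_permutations": config.n_permutations,
            "abundance_weighted": config.abundance_weighted,
            "network": dict(config.network),
            "robustness": dict(config.robustness),
        },
        "stage_seeds": {},
        "outputs": {},
    }
    t0 = time.time()

    def record(name: str, path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
        logger.info("stage=%s wrote=%s elapsed=%.1fs", name, path.name,
                    time.time() - t0)

    try:
        # ------------------------------------------------------------------
        stage = "simulate" if config.synthetic is not None else "ingest"
        seed = stage_seed(config.seed, "simulate")
        manifest["stage_seeds"][stage] = seed
        if config.synthetic is not None:
            sim_cfg = synthetic_data.CommunitySimConfig(
                **{**config.synthetic, "seed": seed}
            )
            tree = synthetic_data.simulate_tree(sim_cfg.n_otus, seed)
            table, meta, truth = synthetic_data.simulate_communities(tree, sim_cfg)
            gas = [
                synthetic_data.simulate_depletion(
                    initial_ppmv=40000.0,
                    rate_fraction_per_day=0.09,
                    days=12,
                    noise_sd=400.0,
                    seed=seed + i,
                    microcosm_id=f"{site}_r{r}",
                )
                for i, (site, r) in enumerate(
                    sorted({(row.site, row.replicate)
                            for row in meta.itertuples()})
                )
            ]
            write_otu_table(table, out / "otu_table.tsv")
            write_tree_newick(tree, out / "tree.nwk")
            write_metadata(meta, out / "metadata.csv")
            write_gas_csv(gas, out / "gas.csv")
            _write_json(truth, out / "ground_truth.json")
            for name in ("otu_table.tsv", "tree.nwk", "metadata.csv",
                         "gas.csv", "ground_truth.json"):
                record(stage, out / name)
            gas_map = {s.microcosm_id: s for s in gas}
        else:
            inp = config.inputs
            for key in ("otu_table", "tree", "metadata"):
                if key not in inp:
                    raise StageError(f"stage=ingest missing input {key!r}")
            table = read_otu_table(
                inp["otu_table"], inp.get("orientation", "samples_as_rows")
            )
            tree = read_tree_newick(inp["tree"])
            meta = read_metadata(inp["metadata"])
            gas_map = read_gas_csv(inp["gas"]) if "gas" in inp else {}
            manifest["input_checksums"] = {
                k: _sha256(Path(v))
                for k, v in inp.items()
                if k != "orientation" and Path(v).exists()
            }

        # ------------------------------------------------------------------
        stage = "kinetics"
        if gas_map:
            mop_rows = []
            for mid, series in sorted(gas_map.items()):
                res = kinetics.methane_oxidation_potential(series)
                t90 = kinetics.time_to_fraction_consumed(series, 0.9)
                mop_rows.append(
                    {
                        "microcosm_id": mid,
                        "mop": res.mop,
                        "c_start": res.c_start,
                        "c_end": res.c_end,
                        "elapsed_hours": res.elapsed_hours,
                        "t90_hours": np.nan if t90 is None else t90,
                    }
                )
            mop_df = pd.DataFrame(mop_rows).set_index("microcosm_id")
            _write_tsv(mop_df, out / "kinetics.tsv")
            record(stage, out / "kinetics.tsv")

        # ------------------------------------------------------------------
        stage = "diversity"
        seed = stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = seed
        depth = config.rarefaction_depth or int(table.sample_sums().min())
        rarefied = diversity.rarefy_counts(table, depth, seed)
        rarefied, tree_aligned = align_table_tree(rarefied, tree)
        meta = meta.loc[list(rarefied.sample_ids)]
        alpha = diversity.alpha_diversity(rarefied, tree_aligned)
        _write_tsv(alpha, out / "alpha_diversity.tsv")
        bc = diversity.bray_curtis(rarefied)
        _write_tsv(bc.to_data_frame(), out / "bray_curtis.tsv")
        ord_res = diversity.pcoa(bc)
        _write_tsv(ord_res.coordinates, out / "pcoa_coordinates.tsv")
        _write_tsv(
            pd.DataFrame(
                {
                    "eigenvalue": ord_res.eigenvalues,
                    "proportion_explained": ord_res.proportion_explained,
                },
                index=ord_res.coordinates.columns,
            ),
            out / "pcoa_eigenvalues.tsv",
        )
        anosim_out = {}
        for label in ("site", "wetland_type"):
            res = diversity.anosim(
                bc, meta[label], n_permutations=config.n_permutations, seed=seed
            )
            anosim_out[label] = {
                "r": res.r, "p": res.p, "n_permutations": res.n_permutations
            }
        _write_json(anosim_out, out / "anosim.json")
        if meta["mop"].notna().any():
            gt = diversity.group_tests(meta["mop"], meta["site"])
            _write_json(
                {"mop_by_site": {"method": gt.method,
                                 "statistic": gt.statistic, "p": gt.p}},
                out / "mop_group_tests.json",
            )
            record(stage, out / "mop_group_tests.json")
        for name in ("alpha_diversity.tsv", "bray_curtis.tsv",
                     "pcoa_coordinates.tsv", "pcoa_eigenvalues.tsv",
                     "anosim.json"):
            record(stage, out / name)

        # ------------------------------------------------------------------
        stage = "assembly"
        seed = stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = seed
        ses = assembly.ses_mpd(
            rarefied, tree_aligned, n_null=config.n_null,
            abundance_weighted=config.abundance_weighted, seed=seed,
        )
        _write_tsv(ses, out / "ses_mpd.tsv")
        bnti = assembly.beta_nti(
            rarefied, tree_aligned, n_null=config.n_null,
            abundance_weighted=config.abundance_weighted, seed=seed,
        )
        rc = assembly.raup_crick_bray(rarefied, n_null=config.n_null, seed=seed)
        pairs = bnti.merge(rc, on=["sample_a", "sample_b"])
        pairs = assembly.classify_assembly_processes(pairs)
        _write_tsv(pairs, out / "assembly_pairs.tsv", index=False)
        for label in ("site", "wetland_type"):
            frac = assembly.process_fractions(pairs, meta[label])
            _write_tsv(frac, out / f"process_fractions_{label}.tsv")
            record(stage, out / f"process_fractions_{label}.tsv")
        if meta["mop"].notna().any():
            reg = assembly.assembly_vs_function(pairs, meta["mop"])
            _write_tsv(reg, out / "assembly_vs_mop.tsv")
            record(stage, out / "assembly_vs_mop.tsv")
        for name in ("ses_mpd.tsv", "assembly_pairs.tsv"):
            record(stage, out / name)

        # ------------------------------------------------------------------
        stage = "network"
        seed = stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = seed
        ncfg = config.network
        filtered = network.filter_taxa(
            rarefied,
            abundance_quantile=ncfg.get("abundance_quantile", 0.10),
            occurrence_fraction=ncfg.get("occurrence_fraction", 0.25),
        )
        clr = network.clr_transform(
            filtered, pseudocount=ncfg.get("pseudocount", 1.0)
        )
        net = network.infer_network(
            clr,
            stars_threshold=ncfg.get("stars_threshold", 0.05),
            n_subsamples=ncfg.get("n_subsamples", 20),
            seed=seed,
        )
        network.annotate_abundance(net, filtered)
        rcfg = config.robustness
        fractions = np.arange(
            0.0, rcfg.get("max_fraction", 0.80) + 1e-9, rcfg.get("step", 0.05)
        )
        networks = {"total": net}
        for wtype in sorted(meta["wetland_type"].unique()):
            subset = meta.index[meta["wetland_type"] == wtype].tolist()
            try:
                networks[wtype] = network.extract_subnetwork(net, filtered, subset)
            except ValueError:
                logger.info("stage=network empty subnetwork for %s", wtype)
        for name, g in networks.items():
            modules, q = network.detect_modules(g, seed=seed)
            node_df, stats = network.topology(g)
            stats["modularity_q"] = q
            stats["n_modules"] = len(set(modules.values()))
            roles = network.zi_pi(g, modules)
            node_df = node_df.join(roles[["module", "zi", "pi", "role"]])
            edges, nodes_attr = network.network_to_tables(g)
            node_df = node_df.join(nodes_attr, how="left")
            _write_tsv(edges, out / f"network_{name}_edges.tsv", index=False)
            _write_tsv(node_df, out / f"network_{name}_nodes.tsv")
            _write_json(stats, out / f"network_{name}_stats.json")
            g_export = g.copy()
            g_export.graph = {
                k: v
                for k, v in g.graph.items()
                if isinstance(v, (str, int, float, bool))
            }
            nx.write_graphml(g_export, out / f"network_{name}.graphml")
            for suffix in ("edges.tsv", "nodes.tsv"):
                record(stage, out / f"network_{name}_{suffix}")
            record(stage, out / f"network_{name}_stats.json")
            record(stage, out / f"network_{name}.graphml")
            if g.number_of_edges() > 0:
                profiles = network.module_abundance(
                    filtered.select_otus([o for o in filtered.otu_ids
                                          if o in g]),
                    modules,
                )
                _write_tsv(profiles, out / f"module_abundance_{name}.tsv")
                record(stage, out / f"module_abundance_{name}.tsv")
                if meta["mop"].notna().any():
                    prof = profiles.loc[[s for s in profiles.index
                                         if s in meta.index]]
                    try:
                        modreg = network.module_function_regression(
                            prof, meta["mop"]
                        )
                        _write_tsv(modreg, out / f"module_mop_{name}.tsv")
                        record(stage, out / f"module_mop_{name}.tsv")
                    except ValueError as exc:
                        logger.info("stage=network module regression "
                                    "skipped for %s: %s", name, exc)
                rows = []
                for mode in ("random", "targeted_degree"):
                    curve = network.robustness(
                        g, removal_mode=mode, fractions=fractions,
                        n_repeats=rcfg.get("n_repeats", 50), seed=seed,
                    )
                    for f, v in zip(curve.removed_fraction,
                                    curve.natural_connectivity):
                        rows.append({"removal_mode": mode,
                                     "removed_fraction": f,
                                     "natural_connectivity": v})
                _write_tsv(pd.DataFrame(rows),
                           out / f"robustness_{name}.tsv", index=False)
                record(stage, out / f"robustness_{name}.tsv")
    except Exception as exc:
        logger.error("stage=%s failed: %s", stage, exc)
        raise StageError(f"stage={stage}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        logger.removeHandler(file_handler)
        file_handler.close()

    _write_json(manifest, out / "manifest.json")
    return manifest
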