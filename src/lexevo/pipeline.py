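"""End-to-end orchestration of the five analysis stages.

``run_pipeline`` wires binarization -> (optional) Bayesian phylogenetics ->
NeighborNet -> admixture clustering with Evanno DeltaK -> Monmonier
barriers -> isolation-by-barrier Mantel tests, writing every stage's
artifact plus a machine-readable ``summary.json``.  Stage seeds derive
deterministically from the global seed, so a rerun with the same config
reproduces the summary bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import admixture, barrier, cognate, mantel, neighbornet, phylo
from .errors import ConfigError

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "lexicon", "sites", "out_dir", "seed",
    "run_phylo", "run_network", "run_admixture", "run_barrier", "run_mantel",
    "k_min", "k_max", "admix_runs", "admix_burnin", "admix_sweeps",
    "n_barriers", "nperm", "admix_threshold", "gain_frac",
    "phylo_model", "phylo_clock", "chain_length",
}


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    lexicon: str
    sites: str | None = None
    out_dir: str = "lexevo_out"
    seed: int = 1
    run_phylo: bool = False
    run_network: bool = True
    run_admixture: bool = True
    run_barrier: bool = True
    run_mantel: bool = True
    k_min: int = 1
    k_max: int = 6
    admix_runs: int = 10
    admix_burnin: int = 300
    admix_sweeps: int = 700
    n_barriers: int = 5          # initial Monmonier extraction count
    nperm: int = 999
    admix_threshold: float = 0.10
    gain_frac: float = 0.01
    phylo_model: str = "two-state"
    phylo_clock: str = "strict"
    chain_length: int = 5000

    def __post_init__(self):
        if not any((self.run_phylo, self.run_network, self.run_admixture,
                    self.run_barrier, self.run_mantel)):
            raise ConfigError("all stages toggled off")
        if self.nperm < 99:
            raise ConfigError(f"nperm must be >= 99, got {self.nperm}")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ConfigError("invalid K range")
        if self.n_barriers < 1:
            raise ConfigError("n_barriers must be >= 1")
        if (self.run_barrier or self.run_mantel) and not self.sites:
            raise ConfigError("barrier/mantel stages need a sites file")


def validate_config(path: str | Path) -> PipelineConfig:
    """Read a flat key=value config file; unknown keys are rejected."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected key=value, got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in _KNOWN_KEYS:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
        values[key] = val
    hints = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    parsed = {}
    for key, val in values.items():
        hint = hints[key]
        if "bool" in str(hint):
            parsed[key] = val.lower() in ("1", "true", "yes", "on")
        elif "int" in str(hint):
            parsed[key] = int(val)
        elif "float" in str(hint):
            parsed[key] = float(val)
        else:
            parsed[key] = val
    cfg = PipelineConfig(**parsed)
    if not Path(cfg.lexicon).exists():
        raise ConfigError(f"lexicon file not found: {cfg.lexicon}")
    if cfg.sites and not Path(cfg.sites).exists():
        raise ConfigError(f"sites file not found: {cfg.sites}")
    return cfg


def _stage_seed(seed: int, stage: str) -> int:
    import zlib

    return int(np.random.default_rng([seed, zlib.crc32(stage.encode())]).integers(2**31 - 1))


def run_pipeline(cfg: PipelineConfig, lex: cognate.LexiconTable | None = None) -> Path:
    """Run the configured stages; returns the report directory.

    On stage failure the exception is re-raised with the stage name after
    partial outputs are kept on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "stages": []}
    t0 = time.time()
    logf = logging.FileHandler(out / "pipeline.log")
    logf.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("lexevo")
    root.addHandler(logf)
    try:
        stage = "code"
        if lex is None:
            lex = cognate.read_lexicon(cfg.lexicon)
        m = cognate.binarize(lex)
        cognate.write_nexus_characters(m, out / "matrix.nex")
        summary["n_taxa"], summary["n_characters"] = m.shape
        summary["stages"].append(stage)

        if cfg.run_phylo:
            stage = "phylo"
            sub = phylo.SubstitutionModel(kind=cfg.phylo_model)
            clock = phylo.ClockModel(kind=cfg.phylo_clock)
            sample = phylo.mcmc_run(
                m, phylo.PriorConfig(), phylo.ChainConfig(n_iter=cfg.chain_length),
                _stage_seed(cfg.seed, stage), sub=sub, clock=clock)
            mcc, freqs = phylo.mcc_tree(sample)
            (out / "mcc.nwk").write_text(mcc.to_newick() + "\n")
            with open(out / "posterior_trees.nwk", "w") as fh:
                for tr in sample.trees[:: max(1, len(sample.trees) // 500)]:
                    fh.write(tr.to_newick() + "\n")
            supports = [f for c, f in freqs.items() if 1 < len(c) < len(m.taxa)]
            summary["mean_clade_support"] = float(np.mean(supports)) if supports else 1.0
            summary["stages"].append(stage)

        if cfg.run_network:
            stage = "network"
            dham = cognate.hamming_distance(m)
            splits = neighbornet.neighbor_net(dham)
            neighbornet.write_nexus_splits(splits, out / "splits.nex")
            summary["reticulation_score"] = neighbornet.reticulation_score(splits)
            summary["network_fit"] = splits.fit
            summary["stages"].append(stage)

        if cfg.run_admixture:
            stage = "admixture"
            runs_by_k = {}
            for k in range(cfg.k_min, cfg.k_max + 1):
                runs_by_k[k] = admixture.run_k(
                    m, k, cfg.admix_runs, cfg.admix_burnin, cfg.admix_sweeps,
                    _stage_seed(cfg.seed, f"admix{k}"))
            table = admixture.evanno_delta_k(runs_by_k)
            table.to_csv(out / "delta_k.tsv", sep="\t", index=False)
            k_star = admixture.select_k(table)
            q = admixture.mean_q(runs_by_k[k_star])
            q.to_csv(out / "q_matrix.tsv", sep="\t")
            summary["k_star"] = k_star
            summary["admixed_taxa"] = admixture.admixed_taxa(q, cfg.admix_threshold)
            summary["stages"].append(stage)

        net = None
        barriers = []
        if cfg.run_barrier:
            stage = "barrier"
            ids, lonlat = barrier.read_sites(cfg.sites)
            djac = cognate.jaccard_distance(m).submatrix([t for t in ids])
            net = barrier.build_network(ids, lonlat, djac)
            barriers = barrier.extract_barriers(net, cfg.n_barriers)
            (out / "barriers.geojson").write_text(
                json.dumps(barrier.barriers_to_geojson(barriers, net), indent=1))
            with open(out / "barrier_edges.tsv", "w") as fh:
                fh.write("barrier\tsite_a\tsite_b\tdistance\n")
                for bi, b in enumerate(barriers, 1):
                    for e in b.crossed:
                        fh.write(f"{bi}\t{ids[e[0]]}\t{ids[e[1]]}\t"
                                 f"{net.edge_distance[e]:.6g}\n")
            summary["n_barriers_extracted"] = len(barriers)
            summary["stages"].append(stage)

        if cfg.run_mantel:
            stage = "mantel"
            if net is None:
                raise ConfigError("mantel stage requires the barrier stage")
            ids = net.ids
            djac = cognate.jaccard_distance(m).submatrix(list(ids))
            geo = mantel.geo_distance_matrix(ids, net.lonlat)
            mseed = _stage_seed(cfg.seed, stage)
            rows = []
            pearson_r2, kendall_r2 = [], []
            for k in range(1, len(barriers) + 1):
                ind = mantel.barrier_indicator(barriers, net, k)
                for method in ("pearson", "kendall"):
                    res = mantel.mantel(djac, ind, method, cfg.nperm, mseed + k)
                    part = mantel.partial_mantel(djac, ind, geo, method,
                                                 cfg.nperm, mseed + k)
                    rows.append({"k": k, "method": method, "r2": res.r2,
                                 "p": res.p, "partial_r2": part.r2,
                                 "partial_p": part.p})
                    (pearson_r2 if method == "pearson" else kendall_r2).append(res.r2)
            import pandas as pd

            pd.DataFrame(rows).to_csv(out / "mantel.tsv", sep="\t", index=False)
            k_keep = mantel.select_n_barriers(pearson_r2, kendall_r2, cfg.gain_frac)
            summary["n_barriers_retained"] = k_keep
            summary["mantel_pearson_r2"] = pearson_r2
            summary["mantel_kendall_r2"] = kendall_r2
            summary["stages"].append(stage)
    except Exception as exc:
        summary["failed_stage"] = stage
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(logf)
        logf.close()
    log.info("pipeline finished in %.1f s", time.time() - t0)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return out
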