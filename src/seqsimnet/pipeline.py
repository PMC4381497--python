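"""End-to-end pipeline: sequences -> hits -> networks -> reports.

One :class:`PipelineConfig` drives the whole chain with the study's default
settings (length >= 300 bp, per-site dereplication, E < 1e-5 / 60% identity
/ 40% cover hit filters, thresholds 85-99, Louvain level 1, novelty rule at
the 85% network with a 95% mean-identity cutoff, 100 label shuffles per
cluster). Every run writes its resolved configuration and a machine-readable
manifest of counts beside the outputs, and all randomness (generator,
Louvain order, permutations) flows from the single root seed.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .records import SequenceRecord, read_fasta, write_fasta
from .simulate import ScenarioConfig, generate_dataset
from .similarity import (dereplicate, filter_hits, length_filter,
                         pairwise_hits, read_blast_tab, write_blast_tab)
from .network import (Partition, build_network, connected_components,
                      louvain_level1, write_edgelist, write_graphml,
                      write_partition)
from .novelty import novelty_report
from .biogeo import (assortativity_frame, assortativity_scan,
                     cluster_profiles, exclusivity_fractions,
                     pooled_significance, profiles_frame)

DEFAULT_THRESHOLDS = (85.0, 90.0, 95.0, 96.0, 97.0, 98.0, 99.0)


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run."""

    fasta: Optional[str] = None           # input FASTA (or None to simulate)
    blast_tab: Optional[str] = None       # precomputed all-vs-all hits
    scenario: Optional[ScenarioConfig] = None
    thresholds: tuple = DEFAULT_THRESHOLDS
    min_len: int = 300
    max_evalue: float = 1e-5
    min_identity: float = 60.0
    min_cover_frac: float = 0.40
    novelty_threshold: float = 85.0
    novelty_cutoff: float = 95.0
    profile_threshold: float = 99.0
    n_sites: int = 8
    n_perm: int = 100
    alpha: tuple = (0.05, 0.01)
    seed: int = 0
    write_graphml: bool = False
    out_dir: str = "seqsimnet_run"

    def validate(self) -> None:
        if not self.thresholds:
            raise ValueError("threshold list must be non-empty")
        for t in self.thresholds:
            if not 0.0 < t <= 100.0:
                raise ValueError(f"threshold {t} outside (0, 100]")
        if self.fasta is None and self.scenario is None:
            raise ValueError("either an input FASTA or a scenario is required")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if self.scenario is not None:
            d["scenario"] = asdict(self.scenario)
        return d


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write outputs; returns the manifest."""
    config.validate()
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 2 + 2 * len(config.thresholds))

    manifest: dict = {"seqsimnet_version": __version__, "seed": config.seed}

    # --- stage: input / simulate
    if config.scenario is not None:
        scenario = dataclasses.replace(config.scenario)
        records, truth = generate_dataset(scenario)
        write_fasta(records, out / "records.fasta")
        truth.write(out / "truth_records.tsv", out / "truth_species.tsv")
    else:
        records = read_fasta(config.fasta)
    manifest["n_input"] = len(records)

    # --- stage: dataset filters
    records = length_filter(records, min_len=config.min_len)
    manifest["n_post_length_filter"] = len(records)
    records, multiplicity = dereplicate(records)
    manifest["n_dereplicated"] = len(records)

    # --- stage: similarity
    if config.blast_tab is not None:
        hits = read_blast_tab(config.blast_tab)
    else:
        hits = pairwise_hits(records,
                             prescreen_identity=max(0.0, config.min_identity - 5.0))
    hits = filter_hits(hits, records, max_evalue=config.max_evalue,
                       min_identity=config.min_identity,
                       min_cover_frac=config.min_cover_frac)
    write_blast_tab(hits, out / "hits_filtered.tsv")
    manifest["n_hits"] = len(hits)

    # --- stage: networks, partitions, biogeo per threshold
    manifest["thresholds"] = {}
    networks, lc_parts = {}, {}
    for i, t in enumerate(config.thresholds):
        net = build_network(hits, records, threshold=t)
        cc = connected_components(net)
        lc = (louvain_level1(net, seed=seeds[2 + 2 * i]) if net.n_nodes
              else Partition(kind="LC", threshold=t, assignment={}))
        networks[t], lc_parts[t] = net, lc
        tkey = f"{t:g}"
        write_edgelist(net, out / f"edges_{tkey}.tsv")
        write_partition(cc, out / f"partition_cc_{tkey}.tsv")
        write_partition(lc, out / f"partition_lc_{tkey}.tsv")
        if config.write_graphml:
            write_graphml(net, out / f"network_{tkey}.graphml")
        entry = {"nodes": net.n_nodes, "edges": net.n_edges,
                 "n_cc": cc.n_clusters, "n_lc": lc.n_clusters}
        if net.n_nodes:
            frames = []
            for kind, part in (("CC", cc), ("LC", lc)):
                for key in ("site", "habitat"):
                    scan = assortativity_scan(net, part, key,
                                              n_perm=config.n_perm,
                                              seed=seeds[3 + 2 * i])
                    df = assortativity_frame(scan)
                    df.insert(0, "partition", kind)
                    frames.append(df)
                    if kind == "CC" and key == "site":
                        _, p, sig = pooled_significance(scan,
                                                        alpha=config.alpha[0])
                        entry["site_assortativity_pooled_p"] = p
                        entry["site_assortativity_significant"] = sig
            pd.concat(frames, ignore_index=True).to_csv(
                out / f"assortativity_{tkey}.tsv", sep="\t", index=False)
        manifest["thresholds"][tkey] = entry

    # --- stage: novelty (at the permissive threshold)
    t_nov = config.novelty_threshold
    if t_nov in networks:
        net, lc = networks[t_nov], lc_parts[t_nov]
    else:
        net = build_network(hits, records, threshold=t_nov)
        lc = (louvain_level1(net, seed=seeds[0]) if net.n_nodes
              else Partition(kind="LC", threshold=t_nov, assignment={}))
    if net.n_nodes and any(r.epoch == "cultured" for r in records):
        report = novelty_report(net, lc, records, hits=hits,
                                avg_identity_cutoff=config.novelty_cutoff)
        report.write(out)
        manifest["n_novel_communities"] = len(report.novel_communities)

    # --- stage: cluster profiles (at the conspecific threshold)
    t_prof = config.profile_threshold
    net_p = networks.get(t_prof) or build_network(hits, records,
                                                  threshold=t_prof)
    if net_p.n_nodes:
        cc_p = connected_components(net_p)
        profiles = cluster_profiles(cc_p, net_p, n_sites=config.n_sites)
        profiles_frame(profiles).to_csv(out / "cluster_profiles.tsv",
                                        sep="\t", index=False)
        manifest["n_profiled_clusters"] = len(profiles)
        manifest["habitat_exclusivity"] = exclusivity_fractions(
            cc_p, net_p, "habitat")

    with open(out / "config.json", "w") as fh:
        json.dump(config.to_jsonable(), fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
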