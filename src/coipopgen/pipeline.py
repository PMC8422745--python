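"""End-to-end orchestration: run every analysis stage and write the tables.

Nothing numeric is computed here; every statistic comes from one of the
analysis modules. The orchestrator only wires stages together, formats
tables and logs parameters for reproducibility.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .demography import MutationClock, SuddenExpansionModel, mismatch_histogram
from .diversity import population_diversity
from .distances import between_population_distance, neighbor_joining, upgma
from .haplotypes import collapse_haplotypes, included_sites, restrict, site_summary
from .io import Alignment, PopulationMap, read_alignment, read_population_map, \
    write_network, write_newick
from .network import build_tcs_network, central_haplotype, \
    parsimony_connection_limit, write_edge_list
from .neutrality import neutrality_tests
from .structure import amova, pairwise_fst, pairwise_difference_matrix, samova


@dataclass
class PipelineConfig:
    alignment: str | Path
    popmap: str | Path
    out_dir: str | Path
    seed: int
    permutations: int = 1000
    bootstrap_reps: int = 200
    neutrality_reps: int = 1000
    clock: MutationClock = field(default_factory=MutationClock)
    samova_k: int = 2
    run_neutrality: bool = True
    run_mismatch: bool = True
    run_structure: bool = True
    run_trees: bool = True
    run_network: bool = True
    verbose: bool = True


def run_all(cfg: PipelineConfig) -> dict[str, Path]:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_lines = [
        f"coipopgen {__version__}",
        f"seed={cfg.seed} permutations={cfg.permutations} "
        f"bootstrap_reps={cfg.bootstrap_reps} neutrality_reps={cfg.neutrality_reps}",
        f"clock: rate={cfg.clock.rate_per_site_per_year}/site/yr "
        f"generation={cfg.clock.generation_time_years}y sites={cfg.clock.sites}",
        "conventions: complete deletion for S/K/pi; pairwise deletion for K2P; "
        "theta1 cap 99999; one-tailed p-values; negative variance components kept",
    ]

    def stage(name):
        t0 = time.perf_counter()
        if cfg.verbose:
            print(f"[coipopgen] {name} ...", flush=True)
        return t0

    def done(name, t0):
        # wall-clock goes to stdout only, keeping the log byte-reproducible
        if cfg.verbose:
            print(f"[coipopgen] {name} done in {time.perf_counter() - t0:.2f}s",
                  flush=True)
        log_lines.append(f"stage completed: {name}")

    try:
        t0 = stage("read inputs")
        aln = read_alignment(cfg.alignment)
        pm = read_population_map(cfg.popmap)
        pm.require_complete(aln)
        done("read", t0)

        t0 = stage("haplotypes + diversity")
        table = collapse_haplotypes(aln, pm)
        table.to_csv(out / "haplotype_table.csv")
        artifacts["haplotypes"] = out / "haplotype_table.csv"
        ss = site_summary(aln)
        div = population_diversity(aln, pm)
        div.to_csv(out / "diversity.csv", index=False, float_format="%.4f")
        artifacts["diversity"] = out / "diversity.csv"
        log_lines.append(
            f"sites: S={ss.S} informative={ss.parsimony_informative} "
            f"excluded={ss.excluded_sites}; haplotypes={table.n_haplotypes} "
            f"singletons={len(table.singletons())}"
        )
        done("diversity", t0)

        sites = included_sites(aln)
        seqs_of = {
            p: [restrict(s, sites) for sid, s in aln.records
                if pm.assignments[sid] == p]
            for p in pm.populations
        }
        pooled = [restrict(s, sites) for s in aln.sequences]

        neut_rows = []
        if cfg.run_neutrality:
            t0 = stage("neutrality tests")
            for r in neutrality_tests(
                aln, pm, reps=cfg.neutrality_reps, seed=cfg.seed
            ):
                neut_rows.append(r.__dict__)
            done("neutrality", t0)

        mm_rows = []
        if cfg.run_mismatch:
            t0 = stage("mismatch / expansion fits")
            rng = np.random.default_rng(cfg.seed + 1)
            for label, seqs in list(seqs_of.items()) + [("pooled", pooled)]:
                hist = mismatch_histogram(seqs)
                pd.DataFrame(
                    {"differences": np.arange(hist.size), "frequency": hist}
                ).to_csv(out / f"mismatch_{label}.csv", index=False)
                model = SuddenExpansionModel(hist, n=len(seqs))
                fit = model.fit()
                model.goodness_of_fit(fit, reps=cfg.bootstrap_reps, rng=rng)
                fit.apply_clock(cfg.clock)
                mm_rows.append(
                    {
                        "population": label, "tau": fit.tau, "theta0": fit.theta0,
                        "theta1": fit.theta1, "SSD": fit.SSD, "SSD_p": fit.SSD_p,
                        "HRI": fit.HRI, "HRI_p": fit.HRI_p,
                        "t_years": fit.t_years, "t_Ma": fit.t_ma,
                    }
                )
            done("mismatch", t0)

        if neut_rows or mm_rows:
            neut = pd.DataFrame(neut_rows) if neut_rows else pd.DataFrame()
            mm = pd.DataFrame(mm_rows) if mm_rows else pd.DataFrame()
            if not neut.empty and not mm.empty:
                merged = neut.merge(mm, on="population", how="outer")
            else:
                merged = neut if not neut.empty else mm
            merged.to_csv(out / "neutrality_mismatch.csv", index=False,
                          float_format="%.3f")
            artifacts["neutrality_mismatch"] = out / "neutrality_mismatch.csv"

        if cfg.run_structure:
            t0 = stage("AMOVA / SAMOVA / pairwise Phi_ST")
            d = pairwise_difference_matrix(aln)
            pops_vec = [pm.assignments[sid] for sid in aln.sample_ids]
            one = amova(d, pops_vec, permutations=cfg.permutations, seed=cfg.seed)
            sam = samova(d, pops_vec, K=cfg.samova_k,
                         permutations=cfg.permutations, seed=cfg.seed)
            with open(out / "amova.txt", "w") as fh:
                fh.write(one.summary() + "\n\n" + sam.summary() + "\n")
                fh.write(f"\nSAMOVA best K={cfg.samova_k} groups: {sam.groups}\n")
            artifacts["amova"] = out / "amova.txt"
            fst = pairwise_fst(d, pops_vec, permutations=cfg.permutations,
                               seed=cfg.seed)
            fst.to_frame().to_csv(out / "pairwise_phist.csv", float_format="%.4f")
            artifacts["pairwise_phist"] = out / "pairwise_phist.csv"
            done("structure", t0)

        if cfg.run_trees:
            t0 = stage("distances + trees")
            dm, within = between_population_distance(aln, pm)
            dm.to_frame().to_csv(out / "ds_matrix.csv", float_format="%.4f")
            artifacts["ds_matrix"] = out / "ds_matrix.csv"
            write_newick(upgma(dm), out / "upgma.nwk")
            write_newick(neighbor_joining(dm), out / "nj.nwk")
            artifacts["upgma"] = out / "upgma.nwk"
            artifacts["nj"] = out / "nj.nwk"
            done("trees", t0)

        if cfg.run_network:
            t0 = stage("haplotype network")
            limit = parsimony_connection_limit(len(sites))
            net = build_tcs_network(table, limit=limit)
            write_network(net.graph, out / "network.graphml")
            artifacts["network"] = out / "network.graphml"
            write_edge_list(net, out / "network_edges.csv")
            artifacts["network_edges"] = out / "network_edges.csv"
            log_lines.append(
                f"network: limit={limit} central={central_haplotype(net)} "
                f"medians={len(net.median_nodes)}"
            )
            done("network", t0)
    except Exception as exc:  # annotate which stage failed
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    artifacts["log"] = out / "run_log.txt"
    return artifacts
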