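"""Config-driven end-to-end analysis runner.

Executes the full SSR analysis sequence on a GenePop file (or a simulated
dataset): HWE/LD exact tests and null-allele EM, the per-area diversity
table, global and pairwise F-statistics with gene flow, coancestry Ne,
bottleneck tests, AMOVA / Mantel / Nei-UPGMA, admixture clustering and
DAPC. Every stage writes a TSV and a JSON provenance record; a failing
stage is recorded and does not abort independent stages.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    allele_frequencies,
    distance_matrix_km,
    read_genepop,
    read_metadata,
    write_genepop,
)
from .simulate import SimConfig, simulate_dataset

DEFAULT_STAGES = (
    "diversity",
    "hwe",
    "ld",
    "nullalleles",
    "fstats",
    "ne",
    "bottleneck",
    "amova",
    "neitree",
    "mantel",
    "structure",
    "dapc",
)


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one of ``genepop`` / ``simulate``."""

    outdir: str
    seed: int = 0
    genepop: str | None = None
    allele_digits: int = 3
    metadata: str | None = None
    simulate: dict | None = None
    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.genepop is None) == (self.simulate is None):
            raise ValueError("config needs exactly one of 'genepop' or 'simulate'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _rounded(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    return df.round(decimals)


def render_diversity_table(summaries, coancestry=None) -> pd.DataFrame:
    """Per-area diversity table in the conventional column order, values
    rounded to 2 decimals (whole percents for A_e%), with an averages row
    computed from the rendered per-area values."""
    rows = {}
    co = {c.area: c for c in coancestry} if coancestry else {}
    for s in summaries:
        row = {
            "N": s.n,
            "k": s.k,
            "A_ri": round(s.a_ri, 1),
            "A_e": round(s.a_e, 2),
            "A_e_pct": round(s.a_e_pct),
            "A_p": s.a_p,
            "A_r": s.a_r,
            "Ho": round(s.ho, 2),
            "He": round(s.he, 2),
            "FIS": round(s.fis, 2),
            "t_a": round(s.t_a, 2),
        }
        if s.area in co:
            row["Ne"] = round(co[s.area].ne, 2)
            row["Ne_over_N"] = round(co[s.area].ne_over_n, 2)
        rows[s.area] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.loc["Average"] = df.mean(axis=0).round(2)
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in analysis order; returns a dict of
    stage name -> output path or error string."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, str] = {}
    provenance: dict[str, dict] = {}
    rng = np.random.default_rng(config.seed)

    if config.simulate is not None:
        sim = SimConfig(**{**config.simulate, "seed": config.seed})
        dataset, truth = simulate_dataset(sim)
        write_genepop(dataset, outdir / "simulated.gen", config.allele_digits)
        with open(outdir / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(
                {k: v for k, v in asdict(sim).items() if not isinstance(v, np.ndarray)},
                fh,
            )
        # ground-truth table: configured F-statistics, per-locus null rates,
        # bottleneck flags and the generating per-area allele frequencies
        rows = []
        for li, locus in enumerate(dataset.loci):
            states = truth.allele_states[li]
            for ai, area in enumerate(dataset.areas):
                freqs = truth.area_freqs[area][li]
                for s, f in zip(states, freqs):
                    rows.append(
                        {"locus": locus, "area": area, "allele": int(s),
                         "true_freq": round(float(f), 6)}
                    )
        pd.DataFrame(rows).to_csv(outdir / "sim_truth_freqs.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "area": dataset.areas,
                "bottleneck": [truth.bottleneck_flags[a] for a in dataset.areas],
            }
        ).assign(target_fst=truth.fst, target_fis=truth.fis).to_csv(
            outdir / "sim_truth_areas.tsv", sep="\t", index=False
        )
        results["simulate"] = str(outdir / "simulated.gen")
    else:
        dataset = read_genepop(config.genepop, config.allele_digits)
    metadata = read_metadata(config.metadata) if config.metadata else None

    def stage(name: str, fn) -> None:
        if name not in config.stages:
            return
        t0 = time.perf_counter()
        try:
            path = fn()
            results[name] = str(path)
            provenance[name] = {
                "seed": config.seed,
                "params": config.params.get(name, {}),
                "runtime_s": round(time.perf_counter() - t0, 3),
                "version": __version__,
            }
        except Exception as exc:  # stage isolation
            results[name] = f"ERROR: {exc}"
            provenance[name] = {"error": str(exc)}

    p = config.params

    def _diversity():
        from .coancestry import coancestry_summary
        from .diversity import area_summaries

        kw = p.get("diversity", {})
        summaries = area_summaries(
            dataset,
            rare_threshold=kw.get("rare_threshold", 0.05),
            rarefaction_g=kw.get("rarefaction_g"),
            n_perm=kw.get("n_perm", 1000),
            seed=config.seed,
        )
        co = None
        if "ne" in config.stages:
            co = [
                coancestry_summary(dataset, s.area, fis=s.fis) for s in summaries
            ]
            results["ne"] = "merged into diversity table"
        table = render_diversity_table(summaries, co)
        out = outdir / "diversity.tsv"
        table.to_csv(out, sep="\t")
        return out

    def _hwe():
        from .disequilibrium import hwe_grid

        kw = p.get("hwe", {})
        grid = hwe_grid(
            dataset,
            dememorization=kw.get("dememorization", 1000),
            batches=kw.get("batches", 20),
            iterations_per_batch=kw.get("iterations_per_batch", 500),
            seed=config.seed,
        )
        out = outdir / "hwe.tsv"
        grid.values.to_csv(out, sep="\t")
        return out

    def _ld():
        from .disequilibrium import ld_grid

        kw = p.get("ld", {})
        grid = ld_grid(
            dataset,
            dememorization=kw.get("dememorization", 1000),
            batches=kw.get("batches", 20),
            iterations_per_batch=kw.get("iterations_per_batch", 500),
            seed=config.seed,
        )
        out = outdir / "ld.tsv"
        grid.values.to_csv(out, sep="\t", index=False)
        return out

    def _null():
        from .disequilibrium import null_allele_grid

        out = outdir / "null_alleles.tsv"
        null_allele_grid(dataset).to_csv(out, sep="\t")
        return out

    def _fstats():
        from .fstats import global_fstats, pairwise_fst

        kw = p.get("fstats", {})
        gf = global_fstats(
            dataset,
            n_boot=kw.get("n_boot", 10_000),
            n_perm=kw.get("n_perm", 200),
            seed=config.seed,
        )
        out = outdir / "global_fstats.tsv"
        with open(out, "w") as fh:
            fh.write(gf.summary() + "\n")
        pw = pairwise_fst(dataset)
        pd.DataFrame(pw.values, index=pw.areas, columns=pw.areas).to_csv(
            outdir / "pairwise_fst.tsv", sep="\t"
        )
        if kw.get("ena", True):
            pw_ena = pairwise_fst(dataset, ena=True)
            pd.DataFrame(pw_ena.values, index=pw_ena.areas, columns=pw_ena.areas).to_csv(
                outdir / "pairwise_fst_ena.tsv", sep="\t"
            )
        return out

    def _bottleneck():
        from .bottleneck import bottleneck_report

        kw = p.get("bottleneck", {})
        rep = bottleneck_report(
            dataset,
            models=tuple(kw.get("models", ("tpm", "smm"))),
            iterations=kw.get("iterations", 500),
            seed=config.seed,
            exclude_loci=kw.get("exclude_loci"),
        )
        rows = [
            {
                "area": r.area,
                "model": r.model,
                "Hd": r.n_deficit,
                "He": r.n_excess,
                "sign_p": round(r.sign_p, 3),
                "wilcoxon_p": round(r.wilcoxon_p, 3),
            }
            for r in rep.rows
        ]
        out = outdir / "bottleneck.tsv"
        pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
        return out

    def _amova():
        from .structure import amova_two_level

        kw = p.get("amova", {})
        res = amova_two_level(dataset, n_perm=kw.get("n_perm", 1000), seed=config.seed)
        out = outdir / "amova.tsv"
        pd.DataFrame(
            {
                "source": ["among_areas", "within_areas"],
                "mean_square": [round(res.ms_among, 3), round(res.ms_within, 3)],
                "variance_pct": [round(res.pct_among, 3), round(res.pct_within, 3)],
                "phi_st": [round(res.phi_st, 4), ""],
                "pvalue": [res.pvalue, ""],
            }
        ).to_csv(out, sep="\t", index=False)
        return out

    def _neitree():
        from .structure import upgma_bootstrap

        kw = p.get("neitree", {})
        tree = upgma_bootstrap(
            dataset,
            variant=kw.get("variant", "1978"),
            n_boot=kw.get("n_boot", 1000),
            seed=config.seed,
        )
        out = outdir / "nei_upgma.nwk"
        with open(out, "w") as fh:
            fh.write(tree.tree.newick() + "\n")
        pd.DataFrame(tree.distances, index=tree.labels, columns=tree.labels).to_csv(
            outdir / "nei_distance.tsv", sep="\t"
        )
        return out

    def _mantel():
        from .structure import mantel_test, nei_distance

        if metadata is None:
            raise ValueError("mantel stage needs area metadata with coordinates")
        kw = p.get("mantel", {})
        order = {m.label: m for m in metadata}
        geo = distance_matrix_km([order[a] for a in dataset.areas])
        gen = nei_distance(allele_frequencies(dataset), kw.get("variant", "1978"))
        r, pv = mantel_test(geo, gen, n_perm=kw.get("n_perm", 9999), seed=config.seed)
        out = outdir / "mantel.tsv"
        pd.DataFrame({"r": [round(r, 4)], "pvalue": [pv]}).to_csv(
            out, sep="\t", index=False
        )
        return out

    def _structure():
        from .clustering import admixture_gibbs, evanno_delta_k

        kw = p.get("structure", {})
        ks = range(kw.get("k_min", 1), kw.get("k_max", 5) + 1)
        reps = kw.get("replicates", 3)
        sweeps = kw.get("sweeps", 2000)
        burn = kw.get("burn_in", 500)
        runs: dict[int, list[float]] = {}
        best_q = {}
        for K in ks:
            runs[K] = []
            for rep in range(reps):
                run = admixture_gibbs(
                    dataset,
                    K,
                    sweeps=sweeps,
                    burn_in=burn,
                    seed=int(rng.integers(2**31)),
                )
                runs[K].append(run.ln_prob)
                best_q[K] = run
        ev = evanno_delta_k(runs)
        ev.table.to_csv(outdir / "evanno.tsv", sep="\t")
        bq = best_q[ev.best_k]
        qdf = pd.DataFrame(
            bq.q_mean,
            index=bq.individual_ids,
            columns=[f"Q{i + 1}" for i in range(bq.K)],
        )
        qdf.insert(0, "area", bq.area_labels)
        out = outdir / "q_matrix.tsv"
        qdf.to_csv(out, sep="\t")
        return out

    def _dapc():
        from .clustering import dapc as run_dapc

        kw = p.get("dapc", {})
        res = run_dapc(dataset, n_pca=kw.get("n_pca", 10), n_da=kw.get("n_da"))
        df = pd.DataFrame(
            res.coordinates,
            index=res.individual_ids,
            columns=[f"LD{i + 1}" for i in range(res.coordinates.shape[1])],
        )
        df.insert(0, "area", res.groups)
        out = outdir / "dapc.tsv"
        df.to_csv(out, sep="\t")
        return out

    stage("hwe", _hwe)
    stage("ld", _ld)
    stage("nullalleles", _null)
    stage("diversity", _diversity)
    stage("fstats", _fstats)
    stage("bottleneck", _bottleneck)
    stage("amova", _amova)
    stage("neitree", _neitree)
    stage("mantel", _mantel)
    stage("structure", _structure)
    stage("dapc", _dapc)

    with open(outdir / "provenance.json", "w") as fh:
        json.dump({"config_seed": config.seed, "stages": provenance}, fh, indent=2)
    return results
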