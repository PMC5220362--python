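"""End-to-end orchestration: simulate -> reconstruct -> associate ->
distances -> MI -> autocovariance -> compare.

Every stage writes TSV/JSON outputs stamped with the config hash and seed;
`run_pipeline` can resume, skipping the expensive early stages when their
stamps match the current configuration. The summary JSON mirrors the
nested-count accounting of the co-gain analysis (total pairs / both GO
annotated / both non-phage / close / distant) per FDR level.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import association as assoc
from . import autocovariance as ac
from . import distances as dist
from . import io as cio
from . import profiles as prof
from . import reconstruction as rec
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis constants (FDR levels, distance bounds, AC settings) plus
    the simulation config. ``close_bound``/``far_bound`` default to the
    simulator's segment caps — the analogs of the 30 kb / 70 kb bounds."""

    seed: int = 0
    tier: str = "inclusive"
    fdr_alphas: tuple = (0.05, 0.005)
    n_null_reps: int = 3
    close_bound: float = 5_000.0
    far_bound: float = 12_000.0
    mi_cutoffs: tuple = (0.0001, 0.8)
    n_go_cutoffs: tuple = (1, 5)
    frame: int = 10
    bins_per_decade: int = 25
    x_max: float = 30_000.0
    n_ac_genomes: int = 5
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        for a in self.fdr_alphas:
            if not 0 < a < 1:
                raise ValueError("fdr_alphas must lie in (0, 1)")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = PipelineConfig(**{**asdict(self), "seed": seed})
        cfg.simulation = SimulationConfig(**{**asdict(self.simulation), "seed": seed})
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("fdr_alphas", "mi_cutoffs", "n_go_cutoffs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    summary: dict = field(default_factory=dict)
    model: rec.GainLossModel | None = None
    pairs: pd.DataFrame | None = None
    fdr: dict | None = None  # alpha -> FdrResult
    phage_status: pd.Series | None = None
    records: pd.DataFrame | None = None  # occurrence records, FDR[alphas[0]] pairs
    distributions: dict = field(default_factory=dict)  # name -> DistanceDistribution
    soc: dict = field(default_factory=dict)  # (mode, cutoff) -> SocDistribution
    mi_table: pd.DataFrame | None = None


STAGES = ("simulate", "reconstruct", "cogain", "distances", "mi", "ac", "compare", "all")


def _shared_go_counts(go_map: dict) -> Counter:
    term_index: dict = {}
    for fam, terms in go_map.items():
        for t in terms:
            term_index.setdefault(t, []).append(fam)
    shared: Counter = Counter()
    for members in term_index.values():
        for a, b in combinations(sorted(members), 2):
            shared[frozenset((a, b))] += 1
    return shared


def _average_curves(curves: list) -> ac.AcCurve:
    x = curves[0].x
    G = np.mean([c.G for c in curves], axis=0)
    return ac.AcCurve(x=x, G=G, n_sites=sum(c.n_sites for c in curves), frame=curves[0].frame)


def run_pipeline(
    config: PipelineConfig,
    outdir,
    inputs: cio.InputBundle | None = None,
    resume: bool = False,
    stop_after: str | None = None,
) -> PipelineResult:
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cio.config_hash(config.to_dict())
    seed = config.seed
    stamp_path = out / "stamps.json"
    stamps = json.loads(stamp_path.read_text()) if (resume and stamp_path.exists()) else {}
    new_stamps: dict = {}

    # ---- stage: simulate / load inputs --------------------------------
    indir = out / "inputs"
    sim_stamp = cio.config_hash({"stage": "simulate", "cfg": asdict(config.simulation)})
    new_stamps["simulate"] = sim_stamp
    if inputs is None:
        if resume and stamps.get("simulate") == sim_stamp and (indir / "tree.nwk").exists():
            logger.info("simulate: resuming from %s", indir)
            inputs = cio.load_inputs(indir)
        else:
            logger.info("simulate: generating dataset (seed=%d)", config.simulation.seed)
            ds = simulate_dataset(config.simulation)
            ds.write(indir)
            inputs = cio.bundle_from_dataset(ds)
    tree, M = inputs.tree, inputs.presence
    logger.info(
        "inputs: %d families x %d genomes, %d branches",
        M.shape[0], M.shape[1], tree.n_branches,
    )

    def _stop(result: PipelineResult) -> PipelineResult:
        stamp_path.write_text(json.dumps(new_stamps, sort_keys=True, indent=1))
        return result

    if stop_after == "simulate":
        return _stop(PipelineResult())

    # ---- stage: reconstruct -------------------------------------------
    rc_stamp = cio.config_hash({"stage": "reconstruct", "up": sim_stamp, "tier": config.tier})
    new_stamps["reconstruct"] = rc_stamp
    post_path = out / "posterior.tsv"
    model_path = out / "model.json"
    if resume and stamps.get("reconstruct") == rc_stamp and post_path.exists():
        logger.info("reconstruct: resuming")
        post = cio.read_table(post_path, index_col=0)
        mj = json.loads(model_path.read_text())
        model = rec.GainLossModel(mj["alpha"], mj["beta"], mj["log_likelihood"])
    else:
        model = rec.fit_model(tree, M)
        logger.info(
            "reconstruct: fitted alpha=%.4f beta=%.4f logL=%.1f",
            model.alpha, model.beta, model.log_likelihood,
        )
        post = rec.posterior_presence(tree, M, model)
        cio.write_table(post, post_path, chash, seed, index=True)
        model_path.write_text(json.dumps(asdict(model), sort_keys=True))
    events = {t: rec.call_events(post, tree, tier=t) for t in ("inclusive", "high")}
    for t, ev in events.items():
        cio.write_table(ev.to_frame(), out / f"events_{t}.tsv", chash, seed)
    if stop_after == "reconstruct":
        return _stop(PipelineResult(model=model))

    # ---- stage: co-gain association ------------------------------------
    cg_stamp = cio.config_hash(
        {"stage": "cogain", "up": rc_stamp, "n_reps": config.n_null_reps, "seed": seed}
    )
    new_stamps["cogain"] = cg_stamp
    pairs_path = out / "pairs.tsv"
    null_path = out / "null_scores.tsv"
    gv = assoc.build_gain_vectors(events[config.tier])
    logger.info("cogain: %d families with >= 1 gain", len(gv))
    null_meta_path = out / "null_meta.json"
    if (
        resume and stamps.get("cogain") == cg_stamp
        and pairs_path.exists() and null_meta_path.exists()
    ):
        logger.info("cogain: resuming")
        pairs = cio.read_table(pairs_path, dtype={"family_a": str, "family_b": str})
        nulldf = cio.read_table(null_path)
        sizes = json.loads(null_meta_path.read_text())["universe_sizes"]
        null = assoc.NullEnsemble(
            scores=[
                nulldf.loc[nulldf["replicate"] == i, "t"].to_numpy()
                for i in range(len(sizes))
            ],
            universe_sizes=sizes,
        )
    else:
        pairs = assoc.score_all_pairs(gv)
        null = assoc.shuffle_null(
            M, tree, model, n_reps=config.n_null_reps, seed=seed + 101, tier=config.tier
        )
        nulldf = pd.concat(
            [pd.DataFrame({"replicate": i, "t": s}) for i, s in enumerate(null.scores)],
            ignore_index=True,
        )
        cio.write_table(nulldf, null_path, chash, seed)
        null_meta_path.write_text(json.dumps({"universe_sizes": null.universe_sizes}))
    fdr = {a: assoc.fdr_threshold(pairs, null, a) for a in config.fdr_alphas}
    for a, res in fdr.items():
        pairs[f"significant_{a}"] = pairs["t"] < res.threshold
        logger.info(
            "cogain: FDR %.3g -> t* = %.4f, %d significant pairs",
            a, res.threshold, len(res.significant),
        )
    cio.write_table(pairs, pairs_path, chash, seed)
    # score CDFs for plotting
    cdf = pd.DataFrame(
        {
            "t": np.sort(pairs["t"]),
            "cdf_empirical": np.arange(1, len(pairs) + 1) / len(pairs),
        }
    )
    cio.write_table(cdf, out / "score_cdf.tsv", chash, seed)
    if stop_after == "cogain":
        return _stop(PipelineResult(model=model, pairs=pairs, fdr=fdr))

    # ---- stage: annotation + distances ---------------------------------
    phage_status = ann.classify_phage(inputs.genes, inputs.go_map)
    ann.write_phage_status(phage_status, out / "phage_status.tsv")
    alpha0 = config.fdr_alphas[0]
    sig0 = fdr[alpha0].significant
    sig_pairs = list(zip(sig0["family_a"], sig0["family_b"]))
    records = dist.pair_occurrence_records(
        sig_pairs, inputs.genes, inputs.genome_lengths, phage_status
    )
    cio.write_table(records, out / "pair_distances.tsv", chash, seed)

    distributions = {}
    np_pairs = dist.non_phage_pairs(sig_pairs, phage_status)
    np_keys = {frozenset(p) for p in np_pairs}
    np_records = records[
        [frozenset((a, b)) in np_keys for a, b in zip(records["family_a"], records["family_b"])]
    ]
    distributions["all_min"] = dist.build_distribution(records, "min", "all")
    distributions["all_occurrence"] = dist.build_distribution(records, "occurrence", "all")
    if len(np_records):
        distributions["non_phage_min"] = dist.build_distribution(np_records, "min", "non_phage")
        distributions["non_phage_occurrence"] = dist.build_distribution(
            np_records, "occurrence", "non_phage"
        )
    truth = inputs.truth
    if truth is not None and len(np_records):
        tr_keys = {
            frozenset((a, b))
            for a, b in np_pairs
            if truth.is_true_pair(a, b)
        }
        tr_records = np_records[
            [
                frozenset((a, b)) in tr_keys
                for a, b in zip(np_records["family_a"], np_records["family_b"])
            ]
        ]
        if len(tr_records):
            distributions["non_phage_truth_min"] = dist.build_distribution(
                tr_records, "min", "non_phage_truth"
            )
    phage_stats = dist.intervening_phage_stats(
        np_records, close_bound=config.close_bound, far_bound=config.far_bound
    )
    logger.info(
        "distances: close mean %.2f%% vs distant mean %.2f%% intervening phage (p=%.3g)",
        phage_stats["close_mean_pct"], phage_stats["distant_mean_pct"], phage_stats["p_value"],
    )
    if stop_after == "distances":
        return _stop(
            PipelineResult(
                model=model, pairs=pairs, fdr=fdr, phage_status=phage_status,
                records=records, distributions=distributions,
            )
        )

    # ---- stage: MI ------------------------------------------------------
    mi_matrix = prof.mi_matrix(inputs.profiles)
    shared = _shared_go_counts(inputs.go_map)
    rows = []
    vals = mi_matrix.to_numpy()
    fam_pos = {f: i for i, f in enumerate(mi_matrix.index)}
    for pair, n_go in shared.items():
        a, b = tuple(pair)
        if a in fam_pos and b in fam_pos:
            rows.append({"family_a": a, "family_b": b, "n_go": n_go,
                         "mi": vals[fam_pos[a], fam_pos[b]]})
    mi_table = pd.DataFrame(rows, columns=["family_a", "family_b", "n_go", "mi"])
    cio.write_table(mi_table, out / "go_mi_pairs.tsv", chash, seed)
    if len(mi_table) >= 3:
        rho, rho_p = prof.go_mi_correlation(mi_table["n_go"], mi_table["mi"])
    else:
        rho, rho_p = np.nan, np.nan
    logger.info("mi: Spearman rho(n_go, MI) = %.3f (p=%.3g)", rho, rho_p)
    if stop_after == "mi":
        return _stop(
            PipelineResult(
                model=model, pairs=pairs, fdr=fdr, phage_status=phage_status,
                records=records, distributions=distributions, mi_table=mi_table,
            )
        )

    # ---- stage: autocovariance / SOC ------------------------------------
    genome_ids = sorted(inputs.genome_lengths)[: config.n_ac_genomes]
    soc: dict = {}
    curves_cache: dict = {}
    for mode, cutoffs in (("CO", config.mi_cutoffs), ("GO", config.n_go_cutoffs)):
        for cut in cutoffs:
            q = ac.PairQualifier(
                mode=mode,
                mi_cutoff=cut if mode == "CO" else 0.0001,
                n_go=int(cut) if mode == "GO" else 1,
            )
            curves = []
            for gid in genome_ids:
                sub = inputs.genes[inputs.genes["genome_id"] == gid]
                pairs_q, elig = ac.qualify_pairs(
                    sub, q, phage_status,
                    mi=mi_matrix if mode == "CO" else None,
                    go_map=inputs.go_map if mode == "GO" else None,
                    operons=inputs.operons.get(gid),
                )
                curves.append(
                    ac.compute_ac(
                        sub, pairs_q, elig, inputs.genome_lengths[gid],
                        frame=config.frame, x_max=config.x_max,
                    )
                )
            curve = _average_curves(curves)
            curves_cache[(mode, cut)] = curve
            try:
                soc[(mode, cut)] = ac.rescale_and_bin(curve, config.bins_per_decade)
            except ac.DegenerateCurveError:
                logger.warning("ac: degenerate %s curve at cutoff %s", mode, cut)
    for (mode, cut), curve in curves_cache.items():
        df = pd.DataFrame({"x": curve.x, "G": curve.G})
        try:
            df["G_tilde"] = curve.G_tilde
        except ac.DegenerateCurveError:
            pass
        cio.write_table(df, out / f"ac_{mode}_{cut}.tsv", chash, seed)
    for (mode, cut), s in soc.items():
        cio.write_table(s.to_frame(), out / f"soc_{mode}_{cut}.tsv", chash, seed)

    operon_dist = ac.operon_distance_distribution(
        {g: inputs.operons.get(g, []) for g in genome_ids},
        inputs.genes[inputs.genes["genome_id"].isin(genome_ids)],
        inputs.genome_lengths,
    )
    distributions["operon"] = operon_dist
    if stop_after == "ac":
        return _stop(
            PipelineResult(
                model=model, pairs=pairs, fdr=fdr, phage_status=phage_status,
                records=records, distributions=distributions, soc=soc, mi_table=mi_table,
            )
        )

    # ---- stage: compare --------------------------------------------------
    comparisons: dict = {}
    cogain_dist = distributions.get("non_phage_min")
    loose_co = soc.get(("CO", config.mi_cutoffs[0]))
    loose_go = soc.get(("GO", config.n_go_cutoffs[0]))
    if cogain_dist is not None and len(cogain_dist):
        if loose_co is not None:
            comparisons["cogain_vs_soc_co"] = ac.compare_distributions(cogain_dist, loose_co)
        if loose_go is not None:
            comparisons["cogain_vs_soc_go"] = ac.compare_distributions(cogain_dist, loose_go)
        if len(operon_dist):
            comparisons["cogain_vs_operon"] = ac.compare_distributions(cogain_dist, operon_dist)
    if loose_co is not None and loose_go is not None:
        comparisons["soc_co_vs_soc_go"] = ac.compare_distributions(loose_co, loose_go)

    # Table-1-style nested counts per FDR level
    counts = {}
    for a, res in fdr.items():
        sig = res.significant
        p_list = list(zip(sig["family_a"], sig["family_b"]))
        both_go = [
            (x, y) for x, y in p_list if inputs.go_map.get(x) and inputs.go_map.get(y)
        ]
        both_np = [
            (x, y) for x, y in both_go
            if phage_status.get(x) == ann.NOT_ASSOCIATED
            and phage_status.get(y) == ann.NOT_ASSOCIATED
        ]
        mind = dist.min_family_distance(records)
        close = distant = 0
        for x, y in both_np:
            key = (x, y) if (x, y) in mind.index else (y, x)
            if key in mind.index:
                if mind[key] < config.close_bound:
                    close += 1
                else:
                    distant += 1
        counts[str(a)] = {
            "total": len(p_list),
            "both_annotated_go": len(both_go),
            "both_not_phage": len(both_np),
            "close": close,
            "distant": distant,
            "threshold_t": res.threshold,
        }

    summary = {
        "config_hash": chash,
        "seed": seed,
        "n_families": int(M.shape[0]),
        "n_genomes": int(M.shape[1]),
        "n_branches": int(tree.n_branches),
        "model": {"alpha": model.alpha, "beta": model.beta,
                  "log_likelihood": model.log_likelihood},
        "counts": counts,
        "phage_stats": phage_stats,
        "go_mi_spearman": {"rho": float(rho), "p": float(rho_p)},
        "medians": {
            "operon": operon_dist.median,
            **{f"soc_{m}_{c}": s.median for (m, c), s in soc.items()},
            **{k: d.median for k, d in distributions.items() if len(d)},
        },
        "comparisons": comparisons,
    }
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    stamp_path.write_text(json.dumps(new_stamps, sort_keys=True, indent=1))
    return PipelineResult(
        summary=summary,
        model=model,
        pairs=pairs,
        fdr=fdr,
        phage_status=phage_status,
        records=records,
        distributions=distributions,
        soc=soc,
        mi_table=mi_table,
    )
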