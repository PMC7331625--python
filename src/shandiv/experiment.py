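"""The resampling experiment: parametric references, subsampling,
relative bias (rB), mean relative squared error (MRSE), sampling-variance
(SD) distributions and their random-pair comparison.

For every replicate and demographic scenario the whole population is
simulated and each metric's *parametric* value is computed on all gene
copies (per locus and as the arithmetic mean over loci).  Samples of
``Ns`` genotypes are then drawn without replacement ``n_resamples`` times;
per draw each metric is evaluated per locus and as the mean over loci.
From these:

* ``rB = (Ĥ - H) / H`` — computed once per metric/scenario/sample size/
  replicate, from the first resample (the parametric value ``H`` is the
  mean-over-loci reference);
* ``MRSE = mean((Ĥ_i - H)^2 / H)`` over the resamples, both for the
  mean-over-loci estimate and per locus;
* ``SD`` — the standard deviation of the mean-over-loci estimate across
  the resamples.

A Chao-Shen (H_CS) failure at any locus makes that draw's mean-over-loci
H_CS missing; missing values are excluded from MRSE/SD (with the number of
contributing resamples recorded) and failures are counted per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._batch import batch_estimates
from ._kernels import draw_subsamples
from .coalsim import SimulationConfig, child_seed, _simulate_population_seeded
from .estimators import METRICS, ChaoShenFailure, _FUNCS
from .popdata import PopulationSample, allele_counts, write_records

log = logging.getLogger(__name__)

H_METRICS = ("H_MLE", "H_Z", "H_CS", "H_Chao")

# stage tags keeping the per-(replicate, scenario) seed key spaces disjoint
_STAGE_SIM = 0
_STAGE_RESAMPLE = 1
_STAGE_COMPARE = 2

__all__ = [
    "H_METRICS",
    "ReferenceValue",
    "ComparisonResult",
    "ReplicateResult",
    "ExperimentResult",
    "SummaryTables",
    "parametric_reference",
    "relative_bias",
    "mrse",
    "run_replicate",
    "run_experiment",
    "compare_sd_distributions",
    "summarize",
    "planned_estimations",
    "write_outputs",
]


@dataclass
class ReferenceValue:
    """Whole-population (parametric) metric values for one scenario."""

    population: str
    replicate: int
    per_locus: pd.DataFrame  # index: locus; columns: METRICS
    means: dict[str, float]  # metric -> arithmetic mean over loci

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "population": self.population,
                "replicate": self.replicate,
                "locus": locus,
                "metric": m,
                "value": self.per_locus.at[locus, m],
            }
            for locus in self.per_locus.index
            for m in self.per_locus.columns
        ] + [
            {
                "population": self.population,
                "replicate": self.replicate,
                "locus": "mean",
                "metric": m,
                "value": v,
            }
            for m, v in self.means.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    """One-sided random-pair comparison of two SD distributions."""

    metric_a: str
    metric_b: str
    population: str
    sample_size: int
    p: float


@dataclass
class ReplicateResult:
    references: pd.DataFrame
    bias: pd.DataFrame
    errors: pd.DataFrame
    sds: pd.DataFrame
    events_per_metric: int
    estimates: pd.DataFrame | None = None


@dataclass
class ExperimentResult:
    config: SimulationConfig
    references: pd.DataFrame
    bias: pd.DataFrame
    errors: pd.DataFrame
    sds: pd.DataFrame
    events_per_metric: int
    estimates: pd.DataFrame | None = None


@dataclass
class SummaryTables:
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    comparisons: pd.DataFrame


def parametric_reference(
    pop: PopulationSample, replicate: int = 0
) -> ReferenceValue:
    """All five metrics per locus on the whole population, plus means.

    A Chao-Shen failure (effectively impossible at whole-population sizes
    but contractually handled) yields a missing per-locus value, which
    propagates to a missing mean.
    """
    if pop.n_individuals == 0:
        raise ValueError("population sample is empty")
    values = {m: [] for m in METRICS}
    for locus in pop.loci:
        c = allele_counts(pop, locus)
        for m in METRICS:
            try:
                values[m].append(_FUNCS[m](c))
            except ChaoShenFailure:
                values[m].append(np.nan)
    per_locus = pd.DataFrame(values, index=pd.Index(pop.loci, name="locus"))
    means = {m: float(np.mean(values[m])) for m in METRICS}
    return ReferenceValue(
        population=pop.population,
        replicate=replicate,
        per_locus=per_locus,
        means=means,
    )


def relative_bias(estimate: float, reference: float) -> float:
    """``(estimate - reference) / reference``; reference must be positive."""
    if not reference > 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    return (estimate - reference) / reference


def mrse(estimates, reference: float) -> tuple[float, int]:
    """Mean relative squared error over the non-missing estimates.

    Returns ``(mean((Ĥ_i - H)^2 / H), m)`` with ``m`` the number of
    non-missing estimates; note the denominator is ``H``, not ``H**2``.
    """
    if not reference > 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    arr = np.asarray(
        [np.nan if e is None else e for e in estimates], dtype=np.float64
    )
    m = int(np.count_nonzero(~np.isnan(arr)))
    if m == 0:
        raise ValueError("all estimates are missing")
    value = float(np.nanmean((arr - reference) ** 2 / reference))
    return value, m


def _pair_copy_indices(individual_idx: np.ndarray) -> np.ndarray:
    """Individual indices (m, ns) -> gene-copy indices (m, 2*ns)."""
    m, ns = individual_idx.shape
    out = np.empty((m, 2 * ns), dtype=np.int64)
    out[:, 0::2] = 2 * individual_idx
    out[:, 1::2] = 2 * individual_idx + 1
    return out


def _counts_matrix(copies: np.ndarray, k_hint: int) -> np.ndarray:
    """Tally each row of allele states into a (rows, k) counts matrix."""
    m, width = copies.shape
    k = max(k_hint, int(copies.max()) + 1)
    offset = np.arange(m, dtype=np.int64)[:, None] * k
    flat = (copies.astype(np.int64) + offset).ravel()
    return np.bincount(flat, minlength=m * k).reshape(m, k)


def run_replicate(
    replicate_id: int, config: SimulationConfig, keep_estimates: bool = False
) -> ReplicateResult:
    """Run one full replicate: simulate every scenario, compute references
    and all subsampled statistics.

    Seeds are derived from ``config.master_seed`` keyed by (replicate,
    scenario, stage, ...), so replicates are reproducible independently and
    in any execution order.
    """
    loci = config.loci
    k_by_locus = [l.k_max for l in loci]
    ref_frames, bias_rows, err_rows, sd_rows, est_rows = [], [], [], [], []

    for s_idx, (scen_name, demog) in enumerate(config.scenarios.items()):
        pop = _simulate_population_seeded(
            demog,
            loci,
            config.pop_size,
            config.master_seed,
            replicate_id,
            s_idx,
            _STAGE_SIM,
            boundary=config.boundary,
        )
        pop.population = scen_name
        ref = parametric_reference(pop, replicate=replicate_id)
        ref_frames.append(ref.to_frame())

        # flat per-locus gene-copy arrays for fast gathering
        copies_by_locus = [
            np.ascontiguousarray(pop.genotypes[:, j, :].reshape(-1))
            for j in range(len(loci))
        ]

        for z_idx, ns in enumerate(config.sample_sizes):
            seed = child_seed(
                config.master_seed, replicate_id, s_idx, _STAGE_RESAMPLE, z_idx
            )
            idx = draw_subsamples(
                config.pop_size, ns, config.n_resamples, seed
            )
            copy_idx = _pair_copy_indices(idx)

            # per-metric (loci, resamples) estimate stacks
            stacks = {
                m: np.empty((len(loci), config.n_resamples)) for m in METRICS
            }
            for j, locus in enumerate(loci):
                counts = _counts_matrix(
                    copies_by_locus[j][copy_idx], k_by_locus[j]
                )
                batch = batch_estimates(counts, METRICS)
                for m in METRICS:
                    stacks[m][j] = batch[m]
                if keep_estimates:
                    for m in METRICS:
                        for r_i, v in enumerate(batch[m]):
                            est_rows.append(
                                (m, scen_name, locus.name, ns,
                                 replicate_id, r_i,
                                 float(v) if np.isfinite(v) else np.nan)
                            )

            for m in METRICS:
                per_locus_ref = ref.per_locus[m].to_numpy()
                ref_mean = ref.means[m]
                over_loci = stacks[m].mean(axis=0)  # NaN if any locus failed
                n_missing = int(np.isnan(over_loci).sum())
                valid = over_loci[~np.isnan(over_loci)]

                # rB from the first resample only
                if np.isnan(over_loci[0]) or not ref_mean > 0:
                    rb = np.nan
                else:
                    rb = relative_bias(float(over_loci[0]), ref_mean)
                bias_rows.append((m, scen_name, ns, replicate_id, rb))

                # mean-over-loci MRSE
                if valid.size and ref_mean > 0:
                    mean_mrse = float(
                        np.mean((valid - ref_mean) ** 2 / ref_mean)
                    )
                else:
                    mean_mrse = np.nan
                err_rows.append(
                    (m, scen_name, ns, replicate_id, "mean",
                     mean_mrse, int(valid.size))
                )
                # per-locus MRSE
                for j, locus in enumerate(loci):
                    h_ref = per_locus_ref[j]
                    row = stacks[m][j]
                    ok = row[~np.isnan(row)]
                    if ok.size and h_ref > 0:
                        v = float(np.mean((ok - h_ref) ** 2 / h_ref))
                    else:
                        v = np.nan
                    err_rows.append(
                        (m, scen_name, ns, replicate_id, locus.name,
                         v, int(ok.size))
                    )

                sd = float(np.std(valid, ddof=1)) if valid.size > 1 else np.nan
                sd_rows.append(
                    (m, scen_name, ns, replicate_id, sd, n_missing)
                )

    events = len(loci) * len(config.scenarios) * (
        len(config.sample_sizes) * config.n_resamples + 1
    )
    return ReplicateResult(
        references=pd.concat(ref_frames, ignore_index=True),
        bias=pd.DataFrame(
            bias_rows,
            columns=["metric", "population", "sample_size", "replicate", "rB"],
        ),
        errors=pd.DataFrame(
            err_rows,
            columns=["metric", "population", "sample_size", "replicate",
                     "locus", "mrse", "m"],
        ),
        sds=pd.DataFrame(
            sd_rows,
            columns=["metric", "population", "sample_size", "replicate",
                     "sd", "n_failures"],
        ),
        events_per_metric=events,
        estimates=pd.DataFrame(
            est_rows,
            columns=["metric", "population", "locus", "sample_size",
                     "replicate", "resample", "value"],
        ) if keep_estimates else None,
    )


def run_experiment(
    config: SimulationConfig,
    progress: bool = False,
    keep_estimates: bool = False,
) -> ExperimentResult:
    """Run all replicates and concatenate their records."""
    iterator = range(config.n_replicates)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="replicates", unit="rep")
    parts: list[ReplicateResult] = []
    cum_failures = 0
    for r in iterator:
        rep = run_replicate(r, config, keep_estimates=keep_estimates)
        cum_failures += int(rep.sds["n_failures"].sum())
        log.info(
            "replicate %d/%d done; cumulative H_CS resampling failures: %d",
            r + 1, config.n_replicates, cum_failures,
        )
        parts.append(rep)
    return ExperimentResult(
        config=config,
        references=pd.concat([p.references for p in parts], ignore_index=True),
        bias=pd.concat([p.bias for p in parts], ignore_index=True),
        errors=pd.concat([p.errors for p in parts], ignore_index=True),
        sds=pd.concat([p.sds for p in parts], ignore_index=True),
        events_per_metric=sum(p.events_per_metric for p in parts),
        estimates=(
            pd.concat([p.estimates for p in parts], ignore_index=True)
            if keep_estimates else None
        ),
    )


def planned_estimations(config: SimulationConfig) -> int:
    """Estimation events per metric for the configured design:
    loci x scenarios x (|sample sizes| * resamples + 1) x replicates."""
    return (
        len(config.loci)
        * len(config.scenarios)
        * (len(config.sample_sizes) * config.n_resamples + 1)
        * config.n_replicates
    )


def compare_sd_distributions(
    a, b, n_pairs: int, rng: np.random.Generator
) -> tuple[float, bool]:
    """One-sided random-pair comparison of two SD distributions.

    Draws ``n_pairs`` independent pairs (one value from each input,
    uniformly with replacement) and returns ``(p, a_lower)`` where ``p`` is
    the fraction of pairs ordered *against* the observed difference of the
    means (ties count against rejection), floored at ``1 / n_pairs``;
    ``a_lower`` reports the direction tested (mean of ``a`` below mean of
    ``b``).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both SD samples must be non-empty")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    draws_a = a[rng.integers(0, a.size, size=n_pairs)]
    draws_b = b[rng.integers(0, b.size, size=n_pairs)]
    a_lower = float(a.mean()) <= float(b.mean())
    if a_lower:
        against = np.count_nonzero(draws_a >= draws_b)
    else:
        against = np.count_nonzero(draws_a <= draws_b)
    p = max(against / n_pairs, 1.0 / n_pairs)
    return float(p), a_lower


def summarize(result: ExperimentResult) -> SummaryTables:
    """Build the three summary tables from experiment records.

    * ``table2``: min/median/max over replicates of the mean-over-loci
      parametric value, per scenario and metric (plus Hs).
    * ``table3``: mean SD per scenario and H metric at the smallest sample
      size, with cells excluded (left missing) where resampling failures
      occurred; ``comparisons`` holds the pairwise random-pair p-values.
    * ``table4``: min/median/max relative bias per sample size and H
      metric, pooled over scenarios and replicates.
    """
    cfg = result.config
    scen_names = list(cfg.scenarios)

    refs = result.references
    mean_refs = refs[refs["locus"] == "mean"]
    t2_rows = []
    for pop in scen_names:
        for m in METRICS:
            v = mean_refs.query("population == @pop and metric == @m")["value"]
            t2_rows.append({
                "population": pop, "metric": m,
                "min": v.min(), "median": v.median(), "max": v.max(),
            })
    table2 = pd.DataFrame(t2_rows)

    ns_min = min(cfg.sample_sizes) if cfg.sample_sizes else None
    t3_rows, cmp_rows = [], []
    if ns_min is not None:
        sds = result.sds.query("sample_size == @ns_min")
        for pop in scen_names:
            cell = {}
            for m in H_METRICS:
                sub = sds.query("population == @pop and metric == @m")
                excluded = bool((sub["n_failures"] > 0).any())
                cell[m] = None if excluded else sub["sd"].to_numpy()
                t3_rows.append({
                    "population": pop, "metric": m, "sample_size": ns_min,
                    "mean_sd": np.nan if excluded else float(np.nanmean(cell[m])),
                    "excluded": excluded,
                })
            for i, ma in enumerate(H_METRICS):
                for mb in H_METRICS[i + 1:]:
                    if cell[ma] is None or cell[mb] is None:
                        continue
                    seed = child_seed(
                        cfg.master_seed, _STAGE_COMPARE,
                        scen_names.index(pop), i, H_METRICS.index(mb),
                    )
                    p, _ = compare_sd_distributions(
                        cell[ma], cell[mb], cfg.sd_comparison_pairs,
                        np.random.default_rng(seed),
                    )
                    cmp_rows.append(ComparisonResult(
                        metric_a=ma, metric_b=mb, population=pop,
                        sample_size=ns_min, p=p,
                    ))
    table3 = pd.DataFrame(t3_rows)
    comparisons = pd.DataFrame([c.__dict__ for c in cmp_rows])

    t4_rows = []
    for ns in cfg.sample_sizes:
        for m in H_METRICS:
            v = result.bias.query("sample_size == @ns and metric == @m")["rB"]
            v = v.dropna()
            t4_rows.append({
                "sample_size": ns, "metric": m,
                "min": v.min() if len(v) else np.nan,
                "median": v.median() if len(v) else np.nan,
                "max": v.max() if len(v) else np.nan,
            })
    table4 = pd.DataFrame(t4_rows)
    return SummaryTables(
        table2=table2, table3=table3, table4=table4, comparisons=comparisons
    )


def write_outputs(result: ExperimentResult, out_dir, tables: SummaryTables | None = None) -> dict[str, int]:
    """Write the record CSVs (and summaries, if given); returns row counts."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    written = {}

    refs = result.references
    he = refs[refs["metric"] == "Hs"].rename(columns={"value": "He_locus"})
    mrse_out = result.errors.merge(
        he[["population", "replicate", "locus", "He_locus"]],
        on=["population", "replicate", "locus"],
        how="left",
    )[["metric", "population", "sample_size", "replicate", "locus",
       "He_locus", "mrse", "m"]]

    frames = {
        "references.csv": refs,
        "bias.csv": result.bias,
        "mrse.csv": mrse_out,
        "sd.csv": result.sds,
    }
    if result.estimates is not None:
        frames["estimates.csv"] = result.estimates
    if tables is not None:
        frames["table2.csv"] = tables.table2
        frames["table3.csv"] = tables.table3
        frames["table4.csv"] = tables.table4
        frames["table3_comparisons.csv"] = tables.comparisons
    for name, frame in frames.items():
        path = os.path.join(out_dir, name)
        write_records(frame, path)
        written[name] = len(frame)
    return written
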