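"""Synthetic study designs and end-to-end analysis pipelines.

Two designs are emulated.  The selfing-series ("maize-like") design
follows two biparental crosses in diploid and tetraploid form through
seven generations of selfing, with trait values reported as deviations
from the cross- and ploidy-specific F1 in five replicate experiments at
generations 0, 1, 3, 5 and 7.  The multi-line panel ("rye-like") design
crosses six inbred lines in all ways — 6 parents, 15 F1 and 120 F2 with
ancestry from P = 2, 3 or 4 lines — in both diploid and synthetic
tetraploid form, reporting cross means only, with a constant
polyploidization cost and a maternal boost for all F2 (grown from F1
seed parents).

Datasets are generated either by simulating the full cross pedigree with
finite cohorts (``noise_sd > 0``) or, in the noiseless case, as the
deterministic infinite-cohort theory means, so that zero-noise data
round-trip exactly through the fitting pipelines.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
import pandas as pd

from . import infer, simulate as sim
from .io import parse_cross
from .theory import (
    LandscapeParams,
    f2_composition,
    selfing_fitness_drop,
)

__all__ = [
    "CrossDesign",
    "enumerate_crosses",
    "MaizeDesign",
    "RyeDesign",
    "gen_maize_dataset",
    "gen_rye_dataset",
    "run_maize_pipeline",
    "run_rye_pipeline",
]


@dataclass(frozen=True)
class CrossDesign:
    """All genotype classes derivable from a set of inbred lines."""

    lines: tuple
    parents: tuple  # canonical cross strings
    f1: tuple
    f2: tuple  # canonical cross strings
    f2_n_parents: dict  # cross string -> P

    @property
    def n_classes(self) -> int:
        return len(self.parents) + len(self.f1) + len(self.f2)


def enumerate_crosses(lines) -> CrossDesign:
    """Parents, all F1 pairs, and all F2 (F1 selfs plus F1 pairs).

    For 6 lines: 15 F1 and 105 + 15 = 120 F2 splitting into 15 / 60 / 45
    classes with P = 2 / 3 / 4 distinct ancestral lines.
    """
    lines = tuple(str(l) for l in lines)
    if len(set(lines)) != len(lines):
        raise ValueError(f"duplicate line labels: {lines}")
    if len(lines) < 2:
        raise ValueError("need at least 2 lines")
    f1_pairs = list(itertools.combinations(sorted(lines), 2))
    f1 = tuple(f"{a}×{b}" for a, b in f1_pairs)
    f2, f2_P = [], {}
    for a, b in f1_pairs:
        s = f"{a}{b}.self"
        f2.append(s)
        f2_P[s] = 2
    for (p1, p2) in itertools.combinations(f1_pairs, 2):
        dam, sire = "".join(p1), "".join(p2)
        s = f"{dam}×{sire}"
        f2.append(s)
        f2_P[s] = len(set(p1) | set(p2))
    return CrossDesign(
        lines=lines,
        parents=tuple(sorted(lines)),
        f1=f1,
        f2=tuple(f2),
        f2_n_parents=f2_P,
    )


# ---------------------------------------------------------------------------
# Selfing-series (maize-like) design


@dataclass(frozen=True)
class MaizeDesign:
    """Study conditions for the selfing-series design.

    Masking coefficients and the noise level live on the transformed
    fitness scale.  ``noise_sd`` is per-plant; each replicate value is
    the mean of a simulated cohort of ``n_plants``.
    """

    crosses: tuple = (("A", "B"), ("C", "D"))
    ploidies: tuple = (2, 4)
    generations: tuple = (0, 1, 3, 5, 7)
    replicates: int = 5
    masking: tuple = (2.0, 1.6)  # M per cross, same at both ploidies
    epistasis: float = 0.4
    noise_sd: float = 0.2
    n_plants: int = 100
    n_loci: int = 100
    seed: int = 0


def _cross_name(pair) -> str:
    return f"{pair[0]}×{pair[1]}"


def gen_maize_dataset(design: MaizeDesign = MaizeDesign(), seed=None, mode="auto") -> pd.DataFrame:
    """Generate a selfing-series trait table (deviations from the F1).

    ``mode="simulate"`` runs single-seed-descent selfing chains through
    the segregation simulator and reports replicate cohort means minus
    the expected F1 value; ``mode="theory"`` emits the deterministic
    theory means; ``mode="auto"`` picks theory when ``noise_sd == 0``.
    """
    if mode == "auto":
        mode = "theory" if design.noise_sd == 0 else "simulate"
    if mode not in ("theory", "simulate"):
        raise ValueError(f"unknown mode {mode!r}")
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rows = []
    for (pair, M) in zip(design.crosses, design.masking):
        name = _cross_name(pair)
        params = LandscapeParams(
            labels=pair,
            parent_fitness=np.zeros(2),
            masking=np.array([[0.0, M], [M, 0.0]]),
            epistasis=np.array([[0.0, design.epistasis], [design.epistasis, 0.0]]),
        )
        for K in design.ploidies:
            if mode == "theory":
                for t in design.generations:
                    drop = float(selfing_fitness_drop(int(t), K, M))
                    for rep in range(1, design.replicates + 1):
                        rows.append((name, K, int(t), rep, drop))
                continue
            # expected F1 value (the reported baseline): (M + I)/4
            f1_mean = (M + design.epistasis) / 4.0
            for rep in range(1, design.replicates + 1):
                cohort = sim.f1_cohort(
                    pair[0], pair[1], design.n_plants, design.n_loci, K, pair
                )
                for t in range(max(design.generations) + 1):
                    if t in design.generations:
                        values = sim.cohort_fitness(
                            cohort, params, noise_sd=design.noise_sd, rng=rng
                        )
                        rows.append((name, K, t, rep, float(values.mean()) - f1_mean))
                    if t < max(design.generations):
                        cohort = sim.self_cohort(cohort, rng)
    df = pd.DataFrame(
        rows, columns=["cross", "ploidy", "generation", "replicate", "value"]
    )
    df.attrs["provenance"] = {"design": asdict(design), "seed": int(seed), "mode": mode}
    return df


# ---------------------------------------------------------------------------
# Multi-line panel (rye-like) design


@dataclass(frozen=True)
class RyeDesign:
    """Study conditions for the six-line, two-ploidy cross-mean panel."""

    lines: tuple = ("A", "B", "C", "D", "E", "F")
    ploidies: tuple = (2, 4)
    # per-line fitness on the transformed (log-yield-like) scale: inbred
    # lines differ severalfold, and that spread is what identifies the
    # common fitness scale across ploidies (a scalar is accepted too)
    w: tuple = (1.0, 1.8, 2.6, 3.4, 4.2, 5.0)
    mbar: float = 2.0
    ibar: float = 0.4
    ploidy_cost: float = -0.5
    maternal_boost: float = 0.3
    noise_sd: float = 0.3
    n_plants: int = 150
    n_loci: int = 100
    drop_missing_f1: bool = True  # mirror the one F1 absent as a tetraploid
    # optionally report the trait as a raw yield (exp of the model
    # scale).  A constant cost on the model scale is then an exact
    # rescaling of the raw trait, so the cross-ploidy r2 criterion
    # cannot distinguish the two scales (both are perfectly linear);
    # the default keeps the reported trait on the model scale.
    raw_scale: bool = False
    seed: int = 0


def _rye_theory_value(cs, K, w_vec, design, lines) -> float:
    """Deterministic cohort mean for one cross under constant M/I."""
    h = cs.h_vector(lines)
    value = float(h @ w_vec)
    s_prod = float((1.0 - (h**2).sum()) / 2.0)
    if cs.kind == "F1":
        s_pair = 0.25
    elif cs.is_f2:
        s_pair = float(f2_composition(K, cs.n_parents).sum_h_pair)
    else:
        s_pair = 0.0
    value += design.mbar * s_pair + design.ibar * s_prod
    if K > 2:
        value += design.ploidy_cost
    if cs.is_f2:
        value += design.maternal_boost
    return value


def gen_rye_dataset(design: RyeDesign = RyeDesign(), seed=None, mode="auto") -> pd.DataFrame:
    """Generate the two-ploidy cross-mean panel (141 classes per ploidy).

    All parents, F1 and F2 are emitted as cohort means; with
    ``drop_missing_f1`` the alphabetically last tetraploid F1 is removed,
    mirroring the single F1 absent in tetraploid form.  Simulation mode
    generates every F2 cohort from the stated pedigree (F1 dam x F1
    sire, or a selfed F1) so the analysis pipeline is exercised end to
    end; the maternal boost is applied to F2 rows (their dam is an F1),
    never inferred from the genotype.
    """
    if mode == "auto":
        mode = "theory" if design.noise_sd == 0 else "simulate"
    if mode not in ("theory", "simulate"):
        raise ValueError(f"unknown mode {mode!r}")
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    lines = tuple(design.lines)
    design_classes = enumerate_crosses(lines)
    w_vec = np.broadcast_to(np.asarray(design.w, dtype=float), (len(lines),)).copy()
    params = LandscapeParams.constant(
        lines, w=w_vec, mbar=design.mbar, ibar=design.ibar
    )
    all_crosses = (
        list(design_classes.parents) + list(design_classes.f1) + list(design_classes.f2)
    )
    missing = f"{lines[-2]}×{lines[-1]}" if design.drop_missing_f1 else None

    def cohort_for(cs, K):
        n, L = design.n_plants, design.n_loci
        if cs.kind == "parent":
            return sim.parent_cohort(cs.dam[0], n, L, K, lines)
        if cs.kind == "F1":
            return sim.f1_cohort(cs.dam[0], cs.sire[0], n, L, K, lines)
        dam = sim.f1_cohort(cs.dam[0], cs.dam[1], n, L, K, lines)
        if cs.kind == "F2-self":
            return sim.self_cohort(dam, rng)
        sire = sim.f1_cohort(cs.sire[0], cs.sire[1], n, L, K, lines)
        return sim.cross_cohort(dam, sire, rng)

    rows = []
    for K in design.ploidies:
        for s in all_crosses:
            if K > 2 and s == missing:
                continue
            cs = parse_cross(s, known_labels=lines)
            if mode == "theory":
                value = _rye_theory_value(cs, K, w_vec, design, lines)
                if design.raw_scale:
                    value = float(np.exp(value))
            else:
                values = sim.cohort_fitness(
                    cohort_for(cs, K),
                    params,
                    noise_sd=design.noise_sd,
                    ploidy_cost=design.ploidy_cost,
                    maternal_boost=design.maternal_boost,
                    dam_is_f1=cs.is_f2,
                    rng=rng,
                )
                if design.raw_scale:
                    values = np.exp(values)
                value = float(values.mean())
            gen = {"parent": 0, "F1": 1, "F2-self": 2, "F2-cross": 2}[cs.kind]
            rows.append((s, K, gen, np.nan, value, cs.n_parents))
    df = pd.DataFrame(
        rows, columns=["cross", "ploidy", "generation", "replicate", "value", "P"]
    )
    df.attrs["provenance"] = {"design": asdict(design), "seed": int(seed), "mode": mode}
    return df


# ---------------------------------------------------------------------------
# Pipelines


def run_maize_pipeline(table: pd.DataFrame) -> dict:
    """Transform, decay fits (per cross and pooled), ploidy scan, class ratio.

    The Box–Cox exponent minimises within-cell skewness over all
    (cross, ploidy, generation) cells; the decay model is then fitted on
    the transformed deviations with one retention rate per ploidy, a
    ploidy scan compares K = 2, 4, 6 at their theoretical rates, and the
    tetraploid heterozygote-class ratio is estimated per cross.
    """
    report: dict = {"analysis": "selfing-series"}
    if "provenance" in table.attrs:
        report["provenance"] = table.attrs["provenance"]
    groups = [
        [cell["value"].to_numpy() for _, cell in gen.groupby(["cross", "ploidy"])]
        for _, gen in table.groupby("generation")
    ]
    spec = infer.choose_lambda_skewmin(groups)
    report["transform"] = {
        "lambda": spec.lam,
        "shift": spec.shift,
        "objective": spec.objective,
        "score": spec.score,
    }
    work = table.copy()
    work["value"] = spec.transform(work["value"])

    report["decay_fits"] = {}
    report["ploidy_scan"] = {}
    residuals = []
    for K, sub in work.groupby("ploidy"):
        fits = {}
        pooled = infer.fit_selfing_decay(sub, ploidy=int(K))
        fits["pooled"] = _decay_summary(pooled)
        fitted = pooled.predict(sub)
        for (_, row), fit in zip(sub.iterrows(), fitted):
            residuals.append(
                {
                    "cross": row["cross"],
                    "ploidy": int(K),
                    "generation": int(row["generation"]),
                    "replicate": row.get("replicate"),
                    "observed": float(row["value"]),
                    "fitted": float(fit),
                    "residual": float(row["value"] - fit),
                }
            )
        for cross, one in sub.groupby("cross"):
            fits[str(cross)] = _decay_summary(infer.fit_selfing_decay(one, ploidy=int(K)))
        report["decay_fits"][str(int(K))] = fits
        scan = infer.ploidy_scan(sub)
        report["ploidy_scan"][str(int(K))] = {
            "logliks": dict(
                zip(scan.table["ploidy"].astype(str), scan.table["loglik"])
            ),
            "best_ploidy": scan.best_ploidy,
        }

    tet = work[work["ploidy"] == 4]
    if len(tet):
        ratios = {}
        for cross, one in tet.groupby("cross"):
            m = infer.fit_het_classes(one)
            ratios[str(cross)] = {
                "b22": m.b22_,
                "b13": m.b13_,
                "ratio": m.ratio_,
                "ratio_se": m.ratio_se_,
                "ratio_ci": list(m.ratio_ci_),
            }
        pooled = infer.fit_het_classes(tet)
        ratios["pooled"] = {
            "b22": pooled.b22_,
            "b13": pooled.b13_,
            "ratio": pooled.ratio_,
            "ratio_se": pooled.ratio_se_,
            "ratio_ci": list(pooled.ratio_ci_),
        }
        report["het_class_ratio"] = ratios
    report["residuals"] = residuals
    return report


def _decay_summary(m) -> dict:
    return {
        "beta": m.beta_,
        "beta_se": m.beta_se_,
        "beta_ci": list(m.beta_ci_),
        "amplitudes": m.amplitudes_.to_dict(),
        "baselines": m.baselines_.to_dict(),
        "rss": m.rss_,
        "loglik": m.loglik_,
        "n": m.n_obs_,
    }


def run_rye_pipeline(table: pd.DataFrame) -> dict:
    """Common-scale transform, SMA + imputation, model selection, heterosis.

    The Box–Cox exponent is chosen to maximise the SMA r2 between the
    diploid and tetraploid means of the fixed genotypes (parents and
    F1); a missing tetraploid F1 is imputed from the fitted SMA line;
    nested mean models (ploidy cost / maternal offset / free tetraploid
    slope) are compared by AIC; and the normalized heterosis contrasts
    are reported with leave-line and leave-pair jackknives.
    """
    report: dict = {"analysis": "multi-line-panel"}
    if "provenance" in table.attrs:
        report["provenance"] = table.attrs["provenance"]
    cl = table.copy()
    kinds = {s: parse_cross(str(s)).kind for s in cl["cross"].unique()}
    cl["_kind"] = [kinds[s] for s in cl["cross"]]
    fixed = cl[cl["_kind"].isin(["parent", "F1"])]
    wide = fixed.pivot_table(index="cross", columns="ploidy", values="value")
    if not {2, 4} <= set(wide.columns):
        raise ValueError("fixed-genotype means for both ploidies are required")
    spec = infer.choose_lambda_sma(wide[2], wide[4])
    report["transform"] = {
        "lambda": spec.lam,
        "shift": spec.shift,
        "objective": spec.objective,
        "r2": spec.score,
    }
    work = table.copy()
    work["value"] = spec.transform(work["value"])

    twide = fixed.assign(value=spec.transform(fixed["value"])).pivot_table(
        index="cross", columns="ploidy", values="value"
    )
    pairs = twide.dropna()
    fit = infer.sma_fit(pairs[2].to_numpy(), pairs[4].to_numpy())
    report["sma"] = {
        "slope": fit.slope_,
        "intercept": fit.intercept_,
        "r2": fit.r2_,
        "n": fit.n_,
    }
    imputed = twide[twide[4].isna() & twide[2].notna()]
    report["imputed"] = {}
    for cross, row in imputed.iterrows():
        y = float(infer.sma_impute(fit, row[2]))
        report["imputed"][str(cross)] = y
        extra = work[(work["cross"] == cross) & (work["ploidy"] == 2)].iloc[:1].copy()
        extra["ploidy"] = 4
        extra["value"] = y
        work = pd.concat([work, extra], ignore_index=True)

    sel = infer.select_rye_model(work)
    report["model_selection"] = {
        "best": sel.best,
        "table": sel.table.to_dict(orient="records"),
        "coefficients": sel.coefficients.to_dict(),
        "n": sel.n_obs,
    }

    het = infer.heterosis_table(work)
    report["heterosis"] = het.to_dict(orient="records")

    def stat(sub):
        t = infer.heterosis_table(sub)
        return pd.Series(
            t["value"].to_numpy(),
            index=[f"K{p}:{c}" for p, c in zip(t["ploidy"], t["contrast"])],
        )

    report["jackknife"] = {}
    for scheme in ("leave-line", "leave-pair"):
        jk = infer.jackknife(work, stat, scheme)
        report["jackknife"][scheme] = {
            "se": jk.se.to_dict(),
            "spread": jk.spread.to_dict(),
            "n_resamples": len(jk.values),
            "failed": jk.failed,
        }
    return report
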