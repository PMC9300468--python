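"""The dual-chemistry subtraction estimator for per-cytosine
(unmodified, m5C, f5C) stoichiometry, replicate aggregation, the
transcriptome-wide modified-site call, and condition comparison.

With ``p_bs`` the protected (unconverted) fraction under plain bisulfite
and ``p_fcab`` the protected fraction under oxime-assisted bisulfite:

    f_m5c   = p_bs
    f_f5c   = max(0, p_fcab - p_bs)
    f_unmod = 1 - max(p_fcab, p_bs)

m5C resists bisulfite in both chemistries; f5C is deaminated by plain
bisulfite but oxime-protected in fCAB, so the fCAB excess over BS is the
f5C fraction.  The clamping handles sampling noise driving the
subtraction negative; the triple always lies on the unit simplex.

No chemistry-efficiency correction is applied by default; an optional
correction dividing protected fractions by calibrated efficiencies is
available but off (see :func:`efficiency_corrected`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ModificationEstimate",
    "estimate_site",
    "estimate_from_counts",
    "estimate_replicates",
    "aggregate_replicates",
    "call_modified_sites",
    "compare_conditions",
    "estimates_frame",
    "estimates_from_frame",
    "NOT_ESTIMABLE",
]

NOT_ESTIMABLE = "NOT_ESTIMABLE"


@dataclass
class ModificationEstimate:
    """Per-site stoichiometry triple with Wilson 95% intervals.

    ``ci_m5c`` is the Wilson interval of ``p_bs``; ``ci_unmod`` the
    reflected Wilson interval of ``max(p_fcab, p_bs)``; ``ci_f5c`` the
    normal-approximation interval of the independent-binomial difference
    ``p_fcab - p_bs``, clipped to [0, 1].  Pooled per-chemistry counts are
    carried along for downstream exact tests and fold changes.
    """

    gene_id: str
    position: int
    f_unmod: float
    f_m5c: float
    f_f5c: float
    p_bs: float
    p_fcab: float
    coverage_bs: int
    coverage_fcab: int
    n_unconverted_bs: int
    n_unconverted_fcab: int
    ci_m5c: tuple[float, float] = (0.0, 1.0)
    ci_f5c: tuple[float, float] = (0.0, 1.0)
    ci_unmod: tuple[float, float] = (0.0, 1.0)
    n_replicates: int = 1
    replicate: int | None = None  # source replicate label, pre-aggregation

    @property
    def triple(self) -> tuple[float, float, float]:
        return (self.f_unmod, self.f_m5c, self.f_f5c)

    @property
    def modified_fraction(self) -> float:
        return self.f_m5c + self.f_f5c


def _triple_from_p(p_bs: float, p_fcab: float) -> tuple[float, float, float]:
    f_m5c = p_bs
    f_f5c = max(0.0, p_fcab - p_bs)
    f_unmod = 1.0 - max(p_fcab, p_bs)
    return f_unmod, f_m5c, f_f5c


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def estimate_from_counts(
    gene_id: str,
    position: int,
    bs_unconverted: int,
    bs_converted: int,
    fcab_unconverted: int,
    fcab_converted: int,
    *,
    n_replicates: int = 1,
) -> ModificationEstimate:
    """Estimate one site from raw (unconverted, converted) count pairs."""
    cov_bs = bs_unconverted + bs_converted
    cov_fcab = fcab_unconverted + fcab_converted
    if cov_bs <= 0 or cov_fcab <= 0:
        raise ZeroDivisionError(
            f"{gene_id}:{position}: zero coverage (BS={cov_bs}, fCAB={cov_fcab})"
        )
    p_bs = bs_unconverted / cov_bs
    p_fcab = fcab_unconverted / cov_fcab
    f_unmod, f_m5c, f_f5c = _triple_from_p(p_bs, p_fcab)

    ci_m5c = _wilson(bs_unconverted, cov_bs)
    if p_fcab >= p_bs:
        hi_n, hi_x = cov_fcab, fcab_unconverted
    else:
        hi_n, hi_x = cov_bs, bs_unconverted
    lo, hi = _wilson(hi_x, hi_n)
    ci_unmod = (1.0 - hi, 1.0 - lo)
    se = float(
        np.sqrt(
            p_fcab * (1 - p_fcab) / cov_fcab + p_bs * (1 - p_bs) / cov_bs
        )
    )
    delta = p_fcab - p_bs
    ci_f5c = (
        float(np.clip(delta - 1.96 * se, 0.0, 1.0)),
        float(np.clip(delta + 1.96 * se, 0.0, 1.0)),
    )
    return ModificationEstimate(
        gene_id=gene_id,
        position=position,
        f_unmod=f_unmod,
        f_m5c=f_m5c,
        f_f5c=f_f5c,
        p_bs=p_bs,
        p_fcab=p_fcab,
        coverage_bs=cov_bs,
        coverage_fcab=cov_fcab,
        n_unconverted_bs=bs_unconverted,
        n_unconverted_fcab=fcab_unconverted,
        ci_m5c=ci_m5c,
        ci_f5c=ci_f5c,
        ci_unmod=ci_unmod,
        n_replicates=n_replicates,
    )


def estimate_site(bs_counts: Mapping, fcab_counts: Mapping):
    """Estimate from two site-count rows (same gene/position, both chemistries).

    Rows are mappings (e.g. DataFrame rows) with gene_id, position,
    n_unconverted and n_converted.  A site with zero coverage in either
    chemistry is reported as :data:`NOT_ESTIMABLE` rather than raising.
    """
    if (bs_counts["gene_id"], bs_counts["position"]) != (
        fcab_counts["gene_id"],
        fcab_counts["position"],
    ):
        raise ValueError("BS and fCAB counts refer to different sites")
    cov_bs = int(bs_counts["n_unconverted"]) + int(bs_counts["n_converted"])
    cov_fcab = int(fcab_counts["n_unconverted"]) + int(fcab_counts["n_converted"])
    if cov_bs == 0 or cov_fcab == 0:
        return NOT_ESTIMABLE
    return estimate_from_counts(
        str(bs_counts["gene_id"]),
        int(bs_counts["position"]),
        int(bs_counts["n_unconverted"]),
        int(bs_counts["n_converted"]),
        int(fcab_counts["n_unconverted"]),
        int(fcab_counts["n_converted"]),
    )


def estimate_replicates(
    counts: pd.DataFrame,
    sites: Iterable[tuple[str, int]] | None = None,
) -> list[ModificationEstimate]:
    """Per-replicate estimates from a long-form site-count table.

    Replicate ids must match across chemistries; sites missing either
    chemistry in a replicate are skipped (NOT_ESTIMABLE).
    """
    wanted = set(sites) if sites is not None else None
    out: list[ModificationEstimate] = []
    indexed = counts.set_index(["gene_id", "position", "chemistry", "replicate"])
    keys = sorted(
        {
            (g, int(p), int(r))
            for g, p, _c, r in indexed.index
            if wanted is None or (g, int(p)) in wanted
        }
    )
    for gene_id, pos, rep in keys:
        try:
            bs = indexed.loc[(gene_id, pos, "BS", rep)]
            fcab = indexed.loc[(gene_id, pos, "FCAB", rep)]
        except KeyError:
            continue
        est = estimate_from_counts(
            gene_id,
            pos,
            int(bs["n_unconverted"]),
            int(bs["n_converted"]),
            int(fcab["n_unconverted"]),
            int(fcab["n_converted"]),
        )
        est.replicate = rep
        out.append(est)
    return out


def aggregate_replicates(
    estimates: Sequence[ModificationEstimate],
    mode: str = "mean_of_fractions",
) -> ModificationEstimate:
    """Combine per-replicate estimates of ONE site into a single estimate.

    ``mean_of_fractions`` (default) averages the per-replicate triples and
    re-applies the simplex clamp via the averaged protected fractions;
    ``pooled_counts`` sums counts across replicates and estimates once.
    Pooled counts and pooled-count Wilson intervals are attached in both
    modes.
    """
    if not estimates:
        raise ValueError("no estimates to aggregate")
    keys = {(e.gene_id, e.position) for e in estimates}
    if len(keys) > 1:
        raise ValueError(f"inconsistent site keys in aggregation: {sorted(keys)}")
    pooled = estimate_from_counts(
        estimates[0].gene_id,
        estimates[0].position,
        sum(e.n_unconverted_bs for e in estimates),
        sum(e.coverage_bs - e.n_unconverted_bs for e in estimates),
        sum(e.n_unconverted_fcab for e in estimates),
        sum(e.coverage_fcab - e.n_unconverted_fcab for e in estimates),
        n_replicates=len(estimates),
    )
    if mode == "pooled_counts":
        return pooled
    if mode != "mean_of_fractions":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    p_bs = float(np.mean([e.p_bs for e in estimates]))
    p_fcab = float(np.mean([e.p_fcab for e in estimates]))
    f_unmod, f_m5c, f_f5c = _triple_from_p(p_bs, p_fcab)
    pooled.p_bs = p_bs
    pooled.p_fcab = p_fcab
    pooled.f_unmod = f_unmod
    pooled.f_m5c = f_m5c
    pooled.f_f5c = f_f5c
    return pooled


def call_modified_sites(
    replicate_estimates: Iterable[ModificationEstimate],
    min_modified_fraction: float = 0.20,
) -> tuple[set[tuple[str, int]], dict[str, list[int]]]:
    """Sites whose modified fraction (m5C + f5C) reaches the threshold in
    every replicate, plus a per-gene summary of flagged positions.

    Feed this per-replicate estimates of sites that already passed the
    coverage filter; a site missing from a replicate is not flagged.
    """
    by_site: dict[tuple[str, int], list[float]] = {}
    n_reps: dict[tuple[str, int], int] = {}
    for est in replicate_estimates:
        key = (est.gene_id, est.position)
        by_site.setdefault(key, []).append(est.modified_fraction)
    max_reps = max((len(v) for v in by_site.values()), default=0)
    flagged = {
        key
        for key, fractions in by_site.items()
        if len(fractions) == max_reps
        and all(f >= min_modified_fraction for f in fractions)
    }
    per_gene: dict[str, list[int]] = {}
    for gene_id, pos in sorted(flagged):
        per_gene.setdefault(gene_id, []).append(pos)
    return flagged, per_gene


def _pseudocounted_unmod(est: ModificationEstimate, pseudocount: float) -> float:
    # Unmodified fraction ~ converted fraction in fCAB; pseudocount keeps
    # the fold change positive and finite at boundary counts.
    conv = est.coverage_fcab - est.n_unconverted_fcab
    return (conv + pseudocount) / (est.coverage_fcab + 2 * pseudocount)


def compare_conditions(
    estimates_a: Sequence[ModificationEstimate],
    estimates_b: Sequence[ModificationEstimate],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-site comparison of condition A vs condition B.

    ``fold_change_unmod`` is the pseudocounted unmodified fraction of A
    over B; ``delta_f5c`` is ``f_f5c(A) - f_f5c(B)``.  The p-value is a
    two-sided Fisher exact test on the pooled fCAB (unconverted,
    converted) table — the chemistry whose converted fraction measures the
    unmodified pool — BH-corrected across tested sites.  Sites present in
    only one condition are reported with ``missing_in`` set and no test.
    """
    a_by_site = {(e.gene_id, e.position): e for e in estimates_a}
    b_by_site = {(e.gene_id, e.position): e for e in estimates_b}
    rows = []
    tested_idx = []
    pvals = []
    for key in sorted(set(a_by_site) | set(b_by_site)):
        a, b = a_by_site.get(key), b_by_site.get(key)
        row = {
            "gene_id": key[0],
            "position": key[1],
            "f_unmod_a": a.f_unmod if a else np.nan,
            "f_unmod_b": b.f_unmod if b else np.nan,
            "f_m5c_a": a.f_m5c if a else np.nan,
            "f_m5c_b": b.f_m5c if b else np.nan,
            "f_f5c_a": a.f_f5c if a else np.nan,
            "f_f5c_b": b.f_f5c if b else np.nan,
            "missing_in": "" if a and b else ("A" if a is None else "B"),
            "fold_change_unmod": np.nan,
            "delta_f5c": np.nan,
            "p_value": np.nan,
            "q_value": np.nan,
        }
        if a and b:
            row["fold_change_unmod"] = _pseudocounted_unmod(
                a, pseudocount
            ) / _pseudocounted_unmod(b, pseudocount)
            row["delta_f5c"] = a.f_f5c - b.f_f5c
            table = [
                [a.n_unconverted_fcab, a.coverage_fcab - a.n_unconverted_fcab],
                [b.n_unconverted_fcab, b.coverage_fcab - b.n_unconverted_fcab],
            ]
            _, p = stats.fisher_exact(table, alternative="two-sided")
            tested_idx.append(len(rows))
            pvals.append(p)
        rows.append(row)
    df = pd.DataFrame(rows)
    if pvals:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for idx, p, q in zip(tested_idx, pvals, qvals):
            df.loc[idx, "p_value"] = p
            df.loc[idx, "q_value"] = q
    return df


def estimates_from_frame(df: pd.DataFrame) -> list[ModificationEstimate]:
    """Rebuild estimate objects from an estimates TSV/DataFrame.

    Fractions and protected fractions are taken as stored (they may be
    mean-of-fraction aggregates); counts feed the exact tests and fold
    changes in :func:`compare_conditions`.
    """
    out = []
    for r in df.itertuples(index=False):
        out.append(
            ModificationEstimate(
                gene_id=str(r.gene_id),
                position=int(r.position),
                f_unmod=float(r.f_unmod),
                f_m5c=float(r.f_m5c),
                f_f5c=float(r.f_f5c),
                p_bs=float(r.p_bs),
                p_fcab=float(r.p_fcab),
                coverage_bs=int(r.coverage_bs),
                coverage_fcab=int(r.coverage_fcab),
                n_unconverted_bs=int(r.n_unconverted_bs),
                n_unconverted_fcab=int(r.n_unconverted_fcab),
                n_replicates=int(getattr(r, "n_replicates", 1)),
            )
        )
    return out


def efficiency_corrected(
    est: ModificationEstimate,
    bs_conversion_efficiency: float,
    oxime_protection_efficiency: float,
) -> ModificationEstimate:
    """Optional chemistry-efficiency correction (off by default).

    Rescales the protected fractions for incomplete conversion and
    protection before re-applying the simplex formulas:
    ``p_bs' = (p_bs - (1 - eff)) / eff`` and similarly for fCAB with the
    oxime protection efficiency applied to the f5C component.
    """
    eff = bs_conversion_efficiency
    p_bs = float(np.clip((est.p_bs - (1 - eff)) / eff, 0.0, 1.0))
    p_fcab = float(np.clip((est.p_fcab - (1 - eff)) / eff, 0.0, 1.0))
    f_unmod, f_m5c, f_f5c = _triple_from_p(p_bs, p_fcab)
    f_f5c = float(np.clip(f_f5c / oxime_protection_efficiency, 0.0, 1.0))
    total = f_unmod + f_m5c + f_f5c
    corrected = ModificationEstimate(
        gene_id=est.gene_id,
        position=est.position,
        f_unmod=f_unmod / total,
        f_m5c=f_m5c / total,
        f_f5c=f_f5c / total,
        p_bs=p_bs,
        p_fcab=p_fcab,
        coverage_bs=est.coverage_bs,
        coverage_fcab=est.coverage_fcab,
        n_unconverted_bs=est.n_unconverted_bs,
        n_unconverted_fcab=est.n_unconverted_fcab,
        n_replicates=est.n_replicates,
    )
    return corrected


def estimates_frame(estimates: Iterable[ModificationEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append(
            {
                "gene_id": e.gene_id,
                "position": e.position,
                "f_unmod": e.f_unmod,
                "f_m5c": e.f_m5c,
                "f_f5c": e.f_f5c,
                "p_bs": e.p_bs,
                "p_fcab": e.p_fcab,
                "ci_m5c_lo": e.ci_m5c[0],
                "ci_m5c_hi": e.ci_m5c[1],
                "ci_f5c_lo": e.ci_f5c[0],
                "ci_f5c_hi": e.ci_f5c[1],
                "ci_unmod_lo": e.ci_unmod[0],
                "ci_unmod_hi": e.ci_unmod[1],
                "coverage_bs": e.coverage_bs,
                "coverage_fcab": e.coverage_fcab,
                "n_unconverted_bs": e.n_unconverted_bs,
                "n_unconverted_fcab": e.n_unconverted_fcab,
                "n_replicates": e.n_replicates,
                "replicate": e.replicate if e.replicate is not None else 0,
            }
        )
    return pd.DataFrame(rows)
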