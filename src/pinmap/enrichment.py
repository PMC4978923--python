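"""Regional variant enrichment statistics.

The enrichment of a variant class in a structural region is scored as the
observed fraction of variants in the region over the fraction of labelled
residues in the region:

    score = (n_r / n) / (N_r / N)

where n_r of n mapped variants fall in region r and N_r of N labelled
residues carry label r.  Significance is assessed two ways:

* an exact one-sided upper-tail hypergeometric p-value (probability of
  drawing at least n_r in-region variants when n positions are drawn
  without replacement from the N labelled residues, N_r of which are in
  the region) — depletion available via ``alternative="less"``;
* a seeded permutation test that redraws the n variant positions uniformly
  over the N labelled residues (with replacement by default, since several
  variants can hit one residue) and recomputes the in-region count;
  p_perm = (1 + #{permutation >= observed}) / (1 + n_perm).

The permutation null is defined over the structurally *labelled* universe,
not the raw sequence, so unresolved positions cannot absorb signal.  An
odds-ratio score is available behind a flag.  Benjamini–Hochberg q-values
are attached across all tested (class × region) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "UndefinedEnrichment",
    "enrichment_score",
    "odds_ratio_score",
    "enrichment_test",
    "adjust_fdr",
    "enrichment_report",
]

DEFAULT_N_PERM = 10_000
DEFAULT_SEED = 17


class UndefinedEnrichment(ZeroDivisionError):
    """Enrichment is undefined (no variants, or empty region)."""


@dataclass(frozen=True)
class EnrichmentInput:
    n_r: int  # variants in region r
    n: int  # total mapped variants
    N_r: int  # residues labelled r
    N: int  # total labelled residues

    def __post_init__(self) -> None:
        if not (0 <= self.n_r <= self.n):
            raise ValueError(f"need 0 <= n_r <= n, got n_r={self.n_r}, n={self.n}")
        if not (0 <= self.N_r <= self.N):
            raise ValueError(f"need 0 <= N_r <= N, got N_r={self.N_r}, N={self.N}")
        if self.N <= 0:
            raise ValueError("N must be positive")


@dataclass
class EnrichmentResult:
    inp: EnrichmentInput
    score: float
    p_exact: float
    p_perm: float
    n_perm: int
    seed: int
    q_value: float = field(default=float("nan"))


def enrichment_score(inp: EnrichmentInput) -> float:
    """Ratio of observed to expected in-region variant fraction."""
    if inp.n == 0 or inp.N_r == 0:
        raise UndefinedEnrichment(
            f"enrichment undefined for n={inp.n}, N_r={inp.N_r}"
        )
    return (inp.n_r / inp.n) / (inp.N_r / inp.N)


def odds_ratio_score(inp: EnrichmentInput) -> float:
    """Haldane-corrected odds ratio, the alternative score behind a flag."""
    a = inp.n_r + 0.5
    b = inp.n - inp.n_r + 0.5
    c = inp.N_r - inp.n_r + 0.5
    d = (inp.N - inp.N_r) - (inp.n - inp.n_r) + 0.5
    return (a / b) / (c / d)


def exact_p(inp: EnrichmentInput, alternative: str = "greater") -> float:
    """One-sided hypergeometric tail probability."""
    if alternative == "greater":
        return float(stats.hypergeom.sf(inp.n_r - 1, inp.N, inp.N_r, inp.n))
    if alternative == "less":
        return float(stats.hypergeom.cdf(inp.n_r, inp.N, inp.N_r, inp.n))
    raise ValueError("alternative must be 'greater' or 'less'")


def enrichment_test(
    inp: EnrichmentInput,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = DEFAULT_SEED,
    region_sizes: dict[str, int] | None = None,
    region: str | None = None,
    with_replacement: bool = True,
    alternative: str = "greater",
    use_odds_ratio: bool = False,
) -> EnrichmentResult:
    """Exact + permutation enrichment test for one (variant class, region) pair.

    ``region_sizes``/``region`` optionally cross-check the input against a
    region census.  The permutation stream uses the counter-based Philox
    generator, so results depend only on ``seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if region_sizes is not None:
        total = sum(region_sizes.values())
        if total != inp.N:
            raise ValueError(
                f"census total {total} inconsistent with N={inp.N}"
            )
        if region is not None and region_sizes.get(region) != inp.N_r:
            raise ValueError(
                f"census count for region {region!r} "
                f"({region_sizes.get(region)}) inconsistent with N_r={inp.N_r}"
            )

    try:
        score = (odds_ratio_score if use_odds_ratio else enrichment_score)(inp)
    except UndefinedEnrichment:
        score = 0.0 if inp.n_r == 0 else float("nan")

    p_ex = exact_p(inp, alternative)

    rng = np.random.Generator(np.random.Philox(seed))
    if inp.n == 0:
        p_perm = 1.0
    elif with_replacement:
        draws = rng.integers(0, inp.N, size=(n_perm, inp.n))
        counts = (draws < inp.N_r).sum(axis=1)
        p_perm = _perm_p(counts, inp.n_r, n_perm, alternative)
    else:
        counts = rng.hypergeometric(inp.N_r, inp.N - inp.N_r, inp.n, size=n_perm)
        p_perm = _perm_p(counts, inp.n_r, n_perm, alternative)

    return EnrichmentResult(
        inp=inp, score=score, p_exact=p_ex, p_perm=p_perm, n_perm=n_perm, seed=seed
    )


def _perm_p(counts: np.ndarray, observed: int, n_perm: int, alternative: str) -> float:
    if alternative == "greater":
        hits = int((counts >= observed).sum())
    else:
        hits = int((counts <= observed).sum())
    return (1 + hits) / (1 + n_perm)


def adjust_fdr(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values (order-preserving)."""
    if len(p_values) == 0:
        return []
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(x) for x in q]


def enrichment_report(
    counts: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = DEFAULT_SEED,
    with_replacement: bool = True,
    alternative: str = "greater",
    use_odds_ratio: bool = False,
) -> pd.DataFrame:
    """Run the test for every row of a (class, region, n_r, n, N_r, N) table.

    Each row gets a distinct sub-seed derived from ``seed`` so permutation
    streams are independent of row order; q-values are BH-adjusted across
    all rows.
    """
    rows = []
    for i, row in enumerate(counts.itertuples(index=False)):
        inp = EnrichmentInput(int(row.n_r), int(row.n), int(row.N_r), int(row.N))
        res = enrichment_test(
            inp,
            n_perm=n_perm,
            seed=(seed + 1000003 * i) % (2**31 - 1),
            with_replacement=with_replacement,
            alternative=alternative,
            use_odds_ratio=use_odds_ratio,
        )
        rows.append(
            {
                "class": getattr(row, "variant_class", getattr(row, "source", "")),
                "region": row.region,
                "n_r": inp.n_r,
                "n": inp.n,
                "N_r": inp.N_r,
                "N": inp.N,
                "score": res.score,
                "p_exact": res.p_exact,
                "p_perm": res.p_perm,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["class", "region", "n_r", "n", "N_r", "N", "score", "p_exact", "p_perm"],
    )
    if len(out):
        out["q"] = adjust_fdr(list(out["p_exact"]))
    else:
        out["q"] = []
    return out
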