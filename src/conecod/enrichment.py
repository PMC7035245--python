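"""Gene-set over-representation by Monte-Carlo resampling and hypergeometric test.

Implements the binding-site target-set enrichment scheme: given a universe
of N genes, a target set S (for example genes with MEF2C binding sites in
retinal open chromatin), and a selection of k genes (the expressed genes,
or the differentially expressed genes), the observed overlap fraction
|S ∩ selection| / |S| is compared against the null obtained by drawing k
genes uniformly without replacement from the universe, repeated
``n_iterations`` times (default 1000).  Three p-values are reported: a
two-tailed one-sample t of the null fractions against the observed value,
an add-one empirical tail probability, and the exact hypergeometric upper
tail.  The closed-form expected fraction is ``|S ∩ U| * k / (N * |S|)``.

:func:`ora` provides generic over-representation of many gene sets against
a query/background pair with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError


@dataclass
class GeneSet:
    name: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name} is empty")
        if len(self.members) != len(set(self.members)):
            raise ValidationError(f"gene set {self.name} has duplicate members")

    @property
    def size(self) -> int:
        return len(self.members)


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gmt(path) -> list[GeneSet]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets.append(GeneSet(parts[0], list(dict.fromkeys(parts[2:]))))
    return sets


@dataclass
class EnrichmentInput:
    """One resampling-enrichment problem.

    ``universe`` has N genes; ``selection`` (k genes) must be a subset of
    it; ``target_set`` members are counted within the universe.
    """

    universe: list[str]
    target_set: GeneSet
    selection: list[str]
    n_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValidationError("universe contains duplicate genes")
        outside = [g for g in self.selection if g not in uni]
        if outside:
            raise ValidationError(
                f"selection not a subset of universe, e.g. {outside[:5]}")
        if len(self.selection) > len(self.universe):
            raise ValidationError("selection larger than universe")


@dataclass
class EnrichmentResult:
    observed_overlap: int
    observed_fraction: float
    null_fractions: np.ndarray = field(repr=False)
    null_mean: float = 0.0
    null_sd: float = 0.0
    expected_fraction_closed_form: float = 0.0
    p_t: float = 1.0
    p_empirical: float = 1.0
    p_hypergeom: float = 1.0
    n_universe: int = 0
    n_target_in_universe: int = 0
    n_selection: int = 0
    n_target: int = 0

    def summary(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "null_fractions"}
        d["n_iterations"] = len(self.null_fractions)
        return d


def overlap_fraction(target_set: GeneSet, selection: list[str]) -> float:
    """|S ∩ selection| / |S| — the full target-set size is the denominator,
    so 34 of a 475-gene set gives 0.0716 (printed as 7.2%)."""
    if target_set.size == 0:
        raise ValidationError("target set is empty")
    return len(set(target_set.members) & set(selection)) / target_set.size


def resampling_null(inp: EnrichmentInput) -> np.ndarray:
    """Null overlap fractions from uniform without-replacement draws.

    Each iteration draws ``len(selection)`` genes from the universe and
    records the overlap fraction with the target set.  Deterministic for a
    fixed seed.
    """
    n = len(inp.universe)
    k = len(inp.selection)
    if k > n:
        raise ValidationError("cannot draw more genes than the universe holds")
    rng = np.random.default_rng(inp.seed)
    member = np.isin(np.asarray(inp.universe, dtype=object),
                     np.asarray(inp.target_set.members, dtype=object))
    fractions = np.empty(inp.n_iterations)
    for i in range(inp.n_iterations):
        draw = rng.choice(n, size=k, replace=False)
        fractions[i] = member[draw].sum() / inp.target_set.size
    return fractions


def enrichment_test(inp: EnrichmentInput) -> EnrichmentResult:
    """Full enrichment result: resampling null, t / empirical / exact p-values.

    ``p_t`` treats the null fractions as a sample and tests it against the
    observed fraction (two-tailed one-sample t, ``n_iterations - 1`` df).
    ``p_empirical`` is the add-one tail estimator, doubled for two tails
    and capped at 1.  ``p_hypergeom`` is the exact upper tail
    ``P(X >= observed)`` of Hypergeometric(N, |S ∩ U|, k).
    """
    if inp.n_iterations < 2:
        raise ValidationError("n_iterations must be >= 2 for the t test")
    member_in_uni = len(set(inp.target_set.members) & set(inp.universe))
    observed = len(set(inp.target_set.members) & set(inp.selection))
    obs_frac = observed / inp.target_set.size
    null = resampling_null(inp)
    n_iter = len(null)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    k = len(inp.selection)
    n_uni = len(inp.universe)
    expected = member_in_uni * k / (n_uni * inp.target_set.size)

    if null_sd == 0:
        p_t = 1.0 if obs_frac == null_mean else 0.0
    else:
        t = (null_mean - obs_frac) / (null_sd / np.sqrt(n_iter))
        p_t = float(2.0 * scipy.stats.t.sf(abs(t), df=n_iter - 1))
    upper = (1 + int((null >= obs_frac).sum())) / (n_iter + 1)
    lower = (1 + int((null <= obs_frac).sum())) / (n_iter + 1)
    p_emp = min(1.0, 2.0 * min(upper, lower))
    p_hyp = float(scipy.stats.hypergeom.sf(observed - 1, n_uni,
                                           member_in_uni, k))
    return EnrichmentResult(
        observed_overlap=observed, observed_fraction=obs_frac,
        null_fractions=null, null_mean=null_mean, null_sd=null_sd,
        expected_fraction_closed_form=expected, p_t=min(p_t, 1.0),
        p_empirical=p_emp, p_hypergeom=p_hyp, n_universe=n_uni,
        n_target_in_universe=member_in_uni, n_selection=k,
        n_target=inp.target_set.size)


def ora(gene_sets: list[GeneSet], query: list[str],
        background: list[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of each set with BH adjustment.

    ``query`` must be a subset of ``background``; sets with no background
    member are excluded with a warning.  Columns: overlap, set size in
    background, expected overlap, fold enrichment, p, adjusted p.
    """
    bg = set(background)
    if len(bg) != len(background):
        raise ValidationError("background contains duplicates")
    outside = [g for g in query if g not in bg]
    if outside:
        raise ValidationError(f"query not a subset of background: {outside[:5]}")
    q = set(query)
    n_bg, n_q = len(bg), len(q)
    rows = []
    for gs in gene_sets:
        in_bg = set(gs.members) & bg
        if not in_bg:
            warnings.warn(f"gene set {gs.name} has no background member; skipped")
            continue
        overlap = len(in_bg & q)
        expected = len(in_bg) * n_q / n_bg
        p = float(scipy.stats.hypergeom.sf(overlap - 1, n_bg, len(in_bg), n_q))
        rows.append({"set": gs.name, "overlap": overlap,
                     "set_in_background": len(in_bg), "expected": expected,
                     "fold": overlap / expected if expected else np.nan, "p": p})
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_in_background",
                                      "expected", "fold", "p"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out
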