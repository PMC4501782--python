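"""Monte-Carlo empirical p-values for candidate-gene list overlap.

Two tests, each run as one million trials of drawing two gene lists
uniformly without replacement from the SNP-tagged gene universe:

* shared-gene test — P(the two lists share at least k genes);
* GO-count test — P(list 1 holds >= k1 and list 2 holds >= k2 genes tagged
  with a given GO term, tags fixed on m of the N genes).

By exchangeability the shared count in one trial is a single hypergeometric
draw (condition on the first list and relabel genes), and likewise each
tagged-in-list count; the trials therefore sample numpy's hypergeometric
generator once (or twice) per trial. Exact tail probabilities are computed
alongside as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

__all__ = ["ResamplingSpec", "shared_gene_pvalue", "go_count_pvalue"]


@dataclass
class ResamplingSpec:
    """Universe and list sizes for a gene-list resampling test.

    ``universe`` is the number of SNP-tagged genes N; ``n1`` and ``n2`` the
    two candidate-list sizes; ``k`` the observed shared-gene count (shared
    test) or ``m``/``k1``/``k2`` the tagged-universe size and observed
    tagged counts (GO-count test).
    """

    universe: int
    n1: int
    n2: int
    k: int | None = None
    m: int | None = None
    k1: int | None = None
    k2: int | None = None
    trials: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 > self.universe or self.n2 > self.universe:
            raise ValueError("list sizes exceed the universe")
        if self.k is not None and self.k > min(self.n1, self.n2):
            raise ValueError("observed overlap exceeds the smaller list")
        if self.m is not None and self.m > self.universe:
            raise ValueError("tagged count m exceeds the universe")


@dataclass
class ResamplingResult:
    p_hat: float
    se: float  # Monte-Carlo standard error of p_hat
    p_exact: float
    trials: int


def shared_gene_pvalue(spec: ResamplingSpec) -> ResamplingResult:
    """Empirical P(two random lists share >= k genes), plus the exact tail.

    The shared count between a fixed list of n1 genes and a uniform draw of
    n2 from N is Hypergeometric(N, n1, n2); each trial draws it once.
    """
    if spec.k is None:
        raise ValueError("spec.k (observed overlap) is required")
    rng = np.random.default_rng(spec.seed)
    overlaps = rng.hypergeometric(
        spec.n1, spec.universe - spec.n1, spec.n2, size=spec.trials
    )
    hits = int(np.sum(overlaps >= spec.k))
    p_hat = hits / spec.trials
    p_exact = float(hypergeom.sf(spec.k - 1, spec.universe, spec.n1, spec.n2))
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / spec.trials))
    return ResamplingResult(p_hat, se, p_exact, spec.trials)


def go_count_pvalue(spec: ResamplingSpec) -> ResamplingResult:
    """Empirical P(list 1 has >= k1 and list 2 has >= k2 tagged genes).

    The two lists are drawn independently, so the exact value is the
    product of two hypergeometric upper tails; each trial draws the two
    tagged counts independently.
    """
    if spec.m is None or spec.k1 is None or spec.k2 is None:
        raise ValueError("spec.m, spec.k1, spec.k2 are required")
    rng = np.random.default_rng(spec.seed)
    t1 = rng.hypergeometric(
        spec.m, spec.universe - spec.m, spec.n1, size=spec.trials
    )
    t2 = rng.hypergeometric(
        spec.m, spec.universe - spec.m, spec.n2, size=spec.trials
    )
    hits = int(np.sum((t1 >= spec.k1) & (t2 >= spec.k2)))
    p_hat = hits / spec.trials
    p_exact = float(
        hypergeom.sf(spec.k1 - 1, spec.universe, spec.m, spec.n1)
        * hypergeom.sf(spec.k2 - 1, spec.universe, spec.m, spec.n2)
    )
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / spec.trials))
    return ResamplingResult(p_hat, se, p_exact, spec.trials)
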