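"""Reliability-based aggregation of multi-item questionnaire blocks.

The six 5-level study variables (physical effort, workload, social
support, personal development, independence, concerns) each summarise a
block of questionnaire items answered on a shared frequency scale
(1 = always ... 5 = never). Internal consistency of a block is measured
by Cronbach's alpha; blocks with alpha >= 0.70 are considered reliable
enough to collapse into a single Likert variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import DKNA_CODE
from .survey import round_half_up

#: Missing-item sentinel inside a block (same convention as DK/NA).
MISSING = 0

ALPHA_ACCEPTABLE = 0.70  # published reliability floor
ALPHA_EXCELLENT = 0.90  # conventional "excellent" cut, not from the survey


class BlockError(ValueError):
    """Raised for degenerate or malformed item blocks."""


@dataclass
class ItemBlock:
    """n x k integer responses (codes 1..5, 0 = missing) to one block."""

    id: str
    responses: np.ndarray
    items: tuple[str, ...] = ()
    target: str | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int64)
        if self.responses.ndim != 2:
            raise BlockError(f"{self.id}: responses must be 2-D")
        if self.responses.shape[1] < 2:
            raise BlockError(f"{self.id}: needs >=2 items")
        valid = (self.responses >= 0) & (self.responses <= 5)
        if not valid.all():
            raise BlockError(f"{self.id}: codes must be in 0..5")
        if self.items and len(self.items) != self.responses.shape[1]:
            raise BlockError(f"{self.id}: item-label count mismatch")

    @property
    def k(self) -> int:
        return self.responses.shape[1]

    @property
    def n(self) -> int:
        return self.responses.shape[0]


@dataclass
class ReliabilityResult:
    """Cronbach alpha of one block with its reliability label."""

    block_id: str
    alpha: float
    k: int
    n_complete: int
    label: str = field(init=False)

    def __post_init__(self) -> None:
        if self.alpha >= ALPHA_EXCELLENT:
            self.label = "excellent"
        elif self.alpha >= ALPHA_ACCEPTABLE:
            self.label = "acceptable"
        else:
            self.label = "unacceptable"


def cronbach_alpha(block: ItemBlock) -> ReliabilityResult:
    """Cronbach's alpha of an item block (listwise-complete rows).

    alpha = k/(k-1) * (1 - sum_i s2_i / s2_total), with unbiased (n-1)
    sample variances of the item columns and of the row totals.
    """
    complete = block.responses[(block.responses != MISSING).all(axis=1)]
    n = complete.shape[0]
    if n < 2:
        raise BlockError(f"{block.id}: fewer than 2 complete rows")
    item_vars = complete.var(axis=0, ddof=1)
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise BlockError(f"{block.id}: degenerate block (zero total variance)")
    k = block.k
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    return ReliabilityResult(block.id, float(alpha), k, n)


def aggregate_block(block: ItemBlock) -> np.ndarray:
    """Collapse a block into one 5-level code per record.

    Per record, the arithmetic mean of the non-missing item codes,
    rounded half-up to the nearest integer in 1..5 (so a 2.5 tie maps
    to 3); a record with every item missing gets the DK/NA sentinel.
    """
    resp = block.responses
    observed = resp != MISSING
    n_obs = observed.sum(axis=1)
    sums = np.where(observed, resp, 0).sum(axis=1)
    out = np.full(block.n, DKNA_CODE, dtype=np.int64)
    has = n_obs > 0
    means = sums[has] / n_obs[has]
    out[has] = [int(round_half_up(m, 0)) for m in means]
    np.clip(out, 0, 5, out=out)
    return out


def block_report(blocks: list[ItemBlock]) -> pd.DataFrame:
    """One reliability row per block, in the given order.

    A degenerate block yields a flagged error row instead of aborting
    the remaining blocks.
    """
    rows = []
    for block in blocks:
        row = {"block": block.id, "target": block.target, "k": block.k}
        try:
            res = cronbach_alpha(block)
            row.update(
                alpha=res.alpha, n_complete=res.n_complete,
                label=res.label, error="",
            )
        except BlockError as exc:
            row.update(alpha=np.nan, n_complete=0, label="", error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_item_block(
    block_id: str,
    n: int,
    k: int,
    rho: float,
    seed: int,
    missing_rate: float = 0.0,
) -> ItemBlock:
    """Sample a correlated ordinal item block for experiments.

    A latent equicorrelated Gaussian (pairwise correlation ``rho``) is
    discretised into the 5-level frequency scale at equispaced normal
    quantiles, so within-block item correlation is controlled.
    """
    if not 0.0 <= rho < 1.0:
        raise BlockError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    common = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, k))
    latent = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * unique
    from scipy.stats import norm

    cuts = norm.ppf([0.2, 0.4, 0.6, 0.8])
    codes = np.digitize(latent, cuts) + 1
    if missing_rate > 0:
        mask = rng.random((n, k)) < missing_rate
        codes[mask] = MISSING
    return ItemBlock(block_id, codes)
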