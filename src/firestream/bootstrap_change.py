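"""Year-resampling bootstrap test for post-fire change in a seasonal index.

The pre-fire years are resampled with replacement into ``n_boot`` subsamples
of three years; each subsample's median forms the null distribution of the
pre-fire index. The post-fire change estimate is the median of the three
post-fire values minus the 500th-ranked (of 1000) subsample median, and the
change is declared significant at the 0.05 level when the post-fire median
falls strictly below the 25th or strictly above the 975th ranked value. Ranks
are 1-based order statistics of the sorted medians, no interpolation.

The test's true level is not the nominal 0.05 (a median of three post years
is compared against order statistics of resampled pre-year medians); the
calibration is characterized by simulation in the test-suite, not corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BootstrapResult", "bootstrap_change_test", "bootstrap_table"]

SUBSAMPLE_SIZE = 3  # pre-fire years drawn per subsample, fixed by the method


@dataclass
class BootstrapResult:
    index_name: str
    season: str
    pre_values: np.ndarray
    post_values: np.ndarray
    n_boot: int
    subsample_medians: np.ndarray  # sorted, length n_boot
    median_reference: float  # rank ceil(n_boot/2) order statistic
    lower_crit: float  # rank round(0.025 n_boot)
    upper_crit: float  # rank round(0.975 n_boot)
    post_median: float
    change_estimate: float
    significant: bool
    alpha: float
    seed: int
    testable: bool = True
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "season": self.season,
                    "index": self.index_name,
                    "change": self.change_estimate,
                    "lower_crit": self.lower_crit,
                    "upper_crit": self.upper_crit,
                    "post_median": self.post_median,
                    "significant": self.significant,
                    "testable": self.testable,
                    "n_boot": self.n_boot,
                    "seed": self.seed,
                    "note": self.note,
                }
            ]
        )


def _order_stat(sorted_values: np.ndarray, rank: int) -> float:
    """1-based order statistic of an ascending array."""
    return float(sorted_values[rank - 1])


def bootstrap_change_test(
    pre_values,
    post_values,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    index_name: str = "",
    season: str = "",
) -> BootstrapResult:
    """Run the year-resampling bootstrap for one seasonal index.

    Requires >= 3 complete pre-fire values and exactly 3 post-fire values
    with no missing data; fully reproducible from ``seed``.
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.size < SUBSAMPLE_SIZE:
        raise ValueError(f"need >= {SUBSAMPLE_SIZE} pre-fire values, got {pre.size}")
    if post.size != 3:
        raise ValueError(f"need exactly 3 post-fire values, got {post.size}")
    if np.isnan(pre).any() or np.isnan(post).any():
        raise ValueError("missing values are not permitted in the bootstrap test")
    if n_boot < 40:
        raise ValueError("n_boot too small for the 2.5%/97.5% rank rule")

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pre.size, size=(n_boot, SUBSAMPLE_SIZE))
    medians = np.sort(np.median(pre[idx], axis=1), kind="stable")

    mid = _order_stat(medians, math.ceil(n_boot / 2))
    lower = _order_stat(medians, int(round(alpha / 2 * n_boot)))
    upper = _order_stat(medians, int(round((1 - alpha / 2) * n_boot)))
    post_median = float(np.median(post))
    return BootstrapResult(
        index_name=index_name,
        season=season,
        pre_values=pre,
        post_values=post,
        n_boot=n_boot,
        subsample_medians=medians,
        median_reference=mid,
        lower_crit=lower,
        upper_crit=upper,
        post_median=post_median,
        change_estimate=post_median - mid,
        significant=bool(post_median < lower or post_median > upper),
        alpha=alpha,
        seed=seed,
    )


def bootstrap_table(
    indices: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> list[BootstrapResult]:
    """One bootstrap test per (season, index) from a seasonal index table.

    A season/index with fewer than 3 non-missing pre-fire years or any
    missing post-fire year is emitted as an untestable row rather than an
    error. Per-test seeds are derived deterministically from ``seed``.
    """
    results = []
    groups = sorted(
        indices.groupby(["season", "index_name"]).groups.keys()
    )
    children = np.random.SeedSequence(seed).spawn(len(groups))
    for (season, index_name), child in zip(groups, children):
        sub = indices[(indices["season"] == season) & (indices["index_name"] == index_name)]
        pre = sub[sub["fire_phase"] == "pre"].sort_values("season_year")["value"]
        post = sub[sub["fire_phase"] == "post"].sort_values("season_year")["value"]
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        pre_ok = pre.notna().sum() >= SUBSAMPLE_SIZE
        post_ok = len(post) == 3 and post.notna().all()
        if not (pre_ok and post_ok):
            results.append(
                BootstrapResult(
                    index_name=index_name,
                    season=season,
                    pre_values=pre.to_numpy(),
                    post_values=post.to_numpy(),
                    n_boot=n_boot,
                    subsample_medians=np.array([]),
                    median_reference=np.nan,
                    lower_crit=np.nan,
                    upper_crit=np.nan,
                    post_median=np.nan,
                    change_estimate=np.nan,
                    significant=False,
                    alpha=0.05,
                    seed=sub_seed,
                    testable=False,
                    note="insufficient non-missing pre/post years",
                )
            )
            continue
        results.append(
            bootstrap_change_test(
                pre.dropna().to_numpy(),
                post.to_numpy(),
                n_boot=n_boot,
                seed=sub_seed,
                index_name=index_name,
                season=season,
            )
        )
    return results
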