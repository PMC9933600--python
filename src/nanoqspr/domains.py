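"""Nested descriptor-domain comparison: core vs core+coating vs core+coating+corona.

Fits one model per nested pool and reports RMSEC and RMSECV side by
side, quantifying how much the coating and protein-corona blocks add
beyond the bare core description of the nanoparticle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ModelingTable
from .ga import GAConfig, run_ga
from .preprocess import DEFAULT_DDOF, fit_autoscaler
from .pls import fit_pls
from .validation import fit_statistics, loo_cross_validate

logger = logging.getLogger(__name__)

NESTED_DOMAINS = (
    ("core", ("core",)),
    ("core+coating", ("core", "coating")),
    ("core+coating+corona", ("core", "coating", "corona")),
)


@dataclass
class DomainComparisonReport:
    """Per-domain error statistics; at most one row per nested pool."""

    table: pd.DataFrame  # domain, descriptors, n_lv, RMSEC, RMSECV

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_domains(
    table: ModelingTable,
    n_lv: int = 2,
    ga_config: GAConfig | None = None,
    ddof: int = DEFAULT_DDOF,
) -> DomainComparisonReport:
    """Fit and cross-validate a model on each nested descriptor pool.

    Without a GA config, each domain uses all descriptors of its pool;
    with one, the GA selects a subset (and LV count) per pool.  The LV
    count is capped by the rank of each pool's scaled training matrix.
    Pools with no columns (e.g. a table without corona descriptors) are
    skipped with a warning.
    """
    rows = []
    present = {c.block for c in table.columns}
    for name, blocks in NESTED_DOMAINS:
        empty = [b for b in blocks if b not in present]
        if empty:
            logger.warning("domain %s: block(s) %s empty in table; skipped", name, empty)
            continue
        pool_table = table.subset_blocks(blocks)
        if ga_config is not None:
            result = run_ga(pool_table, config=ga_config)
            descriptors = result.best_descriptors
            a = result.best_n_lv
        else:
            descriptors = pool_table.descriptor_names
            sub = pool_table
            scaling = fit_autoscaler(sub)
            from .preprocess import apply_autoscaler

            Xs = apply_autoscaler(sub.training() if sub.train_mask.any() else sub, scaling)
            a = min(n_lv, int(np.linalg.matrix_rank(Xs)))
        model = fit_pls(pool_table.subset_descriptors(descriptors), a, ddof=ddof)
        _, rmsec = fit_statistics(model, pool_table.subset_descriptors(descriptors))
        _, rmsecv, _ = loo_cross_validate(
            pool_table, a, descriptors=descriptors, ddof=ddof
        )
        rows.append(
            {
                "domain": name,
                "descriptors": ";".join(descriptors),
                "n_lv": a,
                "RMSEC": rmsec,
                "RMSECV": rmsecv,
            }
        )
    return DomainComparisonReport(table=pd.DataFrame(rows))
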