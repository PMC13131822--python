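"""Exposure refitting against a frozen pretrained model.

New samples' exposures are estimated by running only the variational
E-step (phi, beta) to convergence while the global parameters alpha and
theta stay fixed; the model object is never mutated.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import GenomeBinning
from .ingest import SampleMeta, WeightedCountTensor, build_count_tensor
from .inference import VariationalState, cell_log_topographies, e_step
from .model import ModelState
from .outputs import process_contributions

logger = logging.getLogger(__name__)


def refit_exposures(model: ModelState, Y_new: WeightedCountTensor,
                    binning: GenomeBinning, max_iters: int = 200,
                    tol: float = 1e-10
                    ) -> tuple[np.ndarray, VariationalState]:
    """Exposures and Dirichlet posteriors for new samples, model frozen.

    Empty samples fall back to the prior mean with a logged flag.
    Deterministic given inputs.
    """
    X, t = binning.feature_matrix, binning.availability.counts
    _, cell_logp = cell_log_topographies(model, Y_new, X, t)
    state = e_step(Y_new, model.dirichlet_alpha, cell_logp, None,
                   max_iters=max_iters, tol=tol)
    burdens = Y_new.burdens()
    if np.any(burdens == 0):
        for i in np.where(burdens == 0)[0]:
            logger.warning("sample %s is empty; returning prior-mean exposure",
                           Y_new.sample_ids[i])
            state.beta[i] = model.dirichlet_alpha
    return process_contributions(state), state


def refit_benchmark(model: ModelState, mutations: pd.DataFrame,
                    binning: GenomeBinning, genome: Mapping[str, str],
                    burdens: Sequence[int], seed: int = 0,
                    samples: Sequence[SampleMeta] | None = None,
                    cluster_adjust: bool = True) -> pd.DataFrame:
    """MAE of subsampled-burden exposures against full-data exposures.

    Mutations are subsampled without replacement before weighting; cluster
    detection is re-run on each subsample.  Returns a tidy table
    (sample, burden, mae).
    """
    rng = np.random.default_rng(seed)
    Y_full = build_count_tensor(mutations, binning, genome, samples,
                                cluster_adjust=cluster_adjust)
    full_pi, _ = refit_exposures(model, Y_full, binning)
    order = {s: i for i, s in enumerate(Y_full.sample_ids)}

    rows = []
    for burden in burdens:
        parts = []
        for sid, grp in mutations.groupby("sample", sort=True):
            take = min(int(burden), len(grp))
            idx = rng.choice(len(grp), size=take, replace=False)
            parts.append(grp.iloc[np.sort(idx)])
        sub = pd.concat(parts, ignore_index=True)
        Y_sub = build_count_tensor(sub, binning, genome, samples,
                                   cluster_adjust=cluster_adjust)
        sub_pi, _ = refit_exposures(model, Y_sub, binning)
        for sid in Y_sub.sample_ids:
            i_full = order[sid]
            i_sub = Y_sub.sample_ids.index(sid)
            mae = float(np.abs(full_pi[i_full] - sub_pi[i_sub]).mean())
            rows.append({"sample": sid, "burden": int(burden), "mae": mae})
    return pd.DataFrame(rows)
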