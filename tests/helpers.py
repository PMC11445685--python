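"""Hand-built degenerate model inputs for closed-form checks."""

import numpy as np

from oamodel.cohort import CohortSpec


def degenerate(inputs, q=0.0, uptake=None, revision=0.0, utility=None, discount=None):
    """Clone with hand-set hazards; keeps everything else from the bundle."""
    clone = inputs.clone()
    for sex in clone.mortality_q:
        clone.mortality_q[sex] = np.full_like(clone.mortality_q[sex], q)
    clone.excess_intervals = [(1, None, 1.0)]
    if uptake is not None:
        clone.settings.uptake.p_tkr_year1 = uptake[0]
        clone.settings.uptake.p_tkr_subsequent = uptake[1]
    for key in clone.revision:
        clone.revision[key] = np.full_like(clone.revision[key], revision)
    if utility is not None:
        for key in clone.utilities:
            clone.utilities[key] = np.full(3, utility)
        clone.incremental_utility = np.zeros((3, 3))
    if discount is not None:
        clone.settings.econ.discount_rate = discount
    return clone


def single_stratum_cohort(inputs, n=1.0, props=(0.2, 0.5, 0.3)):
    key = inputs.strata[0].key
    return CohortSpec(
        n_eligible={key: n}, baseline_allocation={key: n * np.asarray(props)}
    )
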