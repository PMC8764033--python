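"""Independent brute-force oracles shared by the HMM tests."""

import numpy as np

from smor.peaks import Peak
from smor.traces import Trace


def make_trace(values, dt=0.1):
    return Trace(Peak(5, 5, 0.0, 0.0), np.asarray(values, dtype=float), dt)


def path_log_prob(model, self_transition, trace, path):
    """Joint log-probability of a state path under the two-state HMM.

    Computed term by term from the model definition -- start probability,
    Gaussian emissions and the symmetric transition matrix -- with no reuse
    of the dynamic-programming code it is used to check.
    """
    mus = np.array([model.mu_unbound, model.mu_bound])
    sigmas = np.array([model.sigma_unbound, model.sigma_bound])
    start = np.array([model.weight_unbound, 1.0 - model.weight_unbound])
    p = self_transition
    trans = np.log(np.array([[p, 1 - p], [1 - p, p]]))
    lp = np.log(start[path[0]])
    for t, s in enumerate(path):
        x = trace[t]
        lp += (-0.5 * ((x - mus[s]) / sigmas[s]) ** 2
               - np.log(sigmas[s] * np.sqrt(2 * np.pi)))
        if t > 0:
            lp += trans[path[t - 1], s]
    return lp
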