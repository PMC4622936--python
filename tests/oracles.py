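"""Independent numerical oracles used by the test suite."""

import numpy as np
from scipy.linalg import expm


def bloch_mcconnell_r2eff(r2_0, pb, dw, kex, nu, t_relax=0.04):
    """Two-site exchange CPMG propagation (numerical dispersion oracle).

    Propagates the complex transverse magnetization of a two-site system
    through a train of (tau - 180deg - tau) echo units with tau = 1/(4 nu)
    and reads out R2_eff = -ln|M(T)| / T.
    """
    pa = 1.0 - pb
    kab, kba = pb * kex, pa * kex
    liouville = np.array(
        [[-kab - r2_0 + 0j, kba], [kab, -kba - r2_0 + 1j * dw]]
    )
    tau = 1.0 / (4.0 * nu)
    n_blocks = int(round(t_relax * 2.0 * nu))
    prop = expm(liouville * tau)
    mag = np.array([pa, pb], dtype=complex)
    for _ in range(n_blocks):
        mag = prop @ np.conj(prop @ mag)
    return -np.log(abs(mag.sum())) / (n_blocks * 2.0 * tau)
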