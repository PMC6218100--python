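import numpy as np
import pytest

from sizecycle import default_params
from sizecycle.dilution import DIL_VARS, CellState, I
from sizecycle.titration import TIT_VARS, TitrationState, J


@pytest.fixture(scope="session")
def dil():
    """Calibrated dilution-model defaults: (params, genome)."""
    return default_params("dilution")


@pytest.fixture(scope="session")
def tit():
    """Calibrated titration-model defaults: (params, genome)."""
    return default_params("titration")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dilution_state(rng, genome, budded=False) -> CellState:
    """A random, physically admissible dilution-model state."""
    y = np.zeros(len(DIL_VARS))
    Vm = rng.uniform(10.0, 40.0)
    Vd = rng.uniform(2.0, 15.0) if budded else 0.0
    y[I["Vm"]], y[I["Vd"]] = Vm, Vd
    y[I["TM"]] = rng.uniform(0.0, 5.0)
    y[I["GITM"]] = rng.uniform(0.0, genome.GIt)
    y[I["GDTM"]] = rng.uniform(0.0, 0.5 * genome.GDt)
    for name in ("CLN3", "CLN", "CLB", "WHI", "WHIp", "WHIn",
                 "CDHi", "CDHa", "CDCi", "CDCa"):
        y[I[name]] = rng.uniform(0.0, 30.0)
    y[I["SBF"]] = rng.uniform(0.0, 40.0)
    y[I["WHISBF"]] = rng.uniform(0.0, 40.0)
    y[I["SBFp"]] = rng.uniform(0.0, y[I["SBF"]] + y[I["WHISBF"]])
    return CellState(y, genome, grm=0 if budded else 1, grd=1 if budded else 0)


def random_titration_state(rng, genome, budded=False) -> TitrationState:
    """A random, physically admissible titration-model state."""
    y = np.zeros(len(TIT_VARS))
    Vm = rng.uniform(5.0, 25.0)
    Vd = rng.uniform(1.0, 8.0) if budded else 0.0
    y[J["Vm"]], y[J["Vd"]] = Vm, Vd
    y[J["TM"]] = rng.uniform(0.0, 3.0)
    y[J["GITM"]] = rng.uniform(0.0, genome.GIt)
    y[J["GDTM"]] = rng.uniform(0.0, 0.5 * genome.GDt)
    for name in ("CLN3", "CLN", "CLB", "WHI", "WHIp", "WHIn",
                 "CDHi", "CDHa", "CDCi", "CDCa"):
        y[J[name]] = rng.uniform(0.0, 15.0)
    # partition the sites among the three bound complexes and free SBF
    shares = rng.dirichlet(np.ones(4)) * genome.NSt
    y[J["WHISBF"]], y[J["CLN3WHISBF"]], y[J["WHIpSBF"]] = shares[:3]
    y[J["SBFp"]] = rng.uniform(0.0, genome.NSt)
    return TitrationState(y, genome, grm=0 if budded else 1, grd=1 if budded else 0)
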