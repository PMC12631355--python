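"""Standard desk-scale simulation protocols.

The production protocol of the models (NPT, 1 fs leapfrog, V-rescale
thermostat, weak pressure coupling at compressibility 4.5e-5 1/bar) is kept;
system size and electrostatics range are reduced to desk scale: 125-molecule
boxes with a 0.65 nm reaction-field cutoff, or 216-molecule boxes with
0.8 nm where longer-range structure (the outer g(r) peaks) is the point.
Half the run is discarded as equilibration when computing averages.
"""

from __future__ import annotations

from .engine import Trajectory, minimize, run
from .models import get_model
from .system import SimulationProtocol, build_box

__all__ = ["desk_run", "DESK_EQUIL_PS", "DESK_PRODUCTION_PS"]

DESK_EQUIL_PS = 20.0
DESK_PRODUCTION_PS = 50.0


def desk_run(model: str, T: float, seed: int, n_molecules: int = 125,
             production_ps: float = DESK_PRODUCTION_PS,
             equil_ps: float = DESK_EQUIL_PS,
             P: float = 1.0) -> tuple[Trajectory, float]:
    """Build, minimize and run one NPT desk-scale simulation.

    Returns the trajectory and the burn-in fraction corresponding to the
    equilibration segment (pass it to the observables).
    """
    spec = get_model(model)
    if n_molecules < 200:
        cutoff = 0.65
    elif n_molecules < 300:
        cutoff = 0.8
    else:
        cutoff = 1.05  # 343-molecule boxes: closest desk scale gets to 1.2 nm
    n_steps = int(round((equil_ps + production_ps) * 1000))
    proto = SimulationProtocol(ensemble="NPT", T_ref=T, P_ref=P,
                               cutoff=cutoff, skin=0.1, seed=seed,
                               n_steps=n_steps, save_every=100)
    config = build_box(spec, n_molecules, target_density=0.99, seed=seed)
    config = minimize(config, proto, max_steps=300, f_tol=500.0)
    traj = run(config, proto)
    burn = equil_ps / (equil_ps + production_ps)
    return traj, burn
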