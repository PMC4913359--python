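"""Canned experiment configurations.

These fixtures span the repertoire of in-silico experiments the simulator
is built for:

* two static contrast edges (0.5 and 0.9) whose limit cycles must differ —
  the contrast-coding experiment;
* a zero-contrast blank field — with no luminance structure the ex-afferent
  loop never closes and the motor equation alone drives the pan to its
  actuator limit;
* a bounded screen with no object in the scanned field — nothing happens at
  all from a quiescent start, the loop stays open;
* a triangle-wave moving edge with a relaxation-regime parameter set —
  the emergent smooth-pursuit experiment.

The pursuit fixture uses stronger nonlinearity (mu = 10 /s) and a slower
small-signal frequency (2 rad/s at the fixture contrast) than the default
quasi-sinusoidal set: dwells at the stimulus velocity only develop when the
relaxation branches of the cycle are slow enough for the pan to linger
where the retinal slip — and hence the sensory drive — vanishes.
"""

from __future__ import annotations

from pathlib import Path

from .config import AnalysisConfig, ExperimentConfig, save_config
from .dynamics import DEFAULT_C1, LoopParams
from .engine import EngineConfig
from .scene import FieldWrap, Scene
from .sensor import SensorConfig

#: edge speed of the moving-edge fixture (deg/s)
PURSUIT_EDGE_SPEED = 5.0
#: half-period of the fixture's triangle-wave edge motion (s)
PURSUIT_HALF_PERIOD = 8.0
#: contrast of the moving-edge fixture
PURSUIT_GAMMA = 0.7


def pursuit_params() -> LoopParams:
    """Relaxation-regime loop constants for the smooth-pursuit experiment.

    c2 is set so the small-signal frequency at the fixture contrast is
    4 rad/s, well below mu = 10 /s.
    """
    c3 = 0.005
    omega0 = 4.0
    return LoopParams(
        c2=omega0**2 * c3 / (DEFAULT_C1 * PURSUIT_GAMMA), c3=c3, mu=10.0
    )


def make_fixtures(output_dir) -> dict[str, Path]:
    """Write the canned experiment configs; returns {name: path}."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures = {
        "static_edge_gamma05": ExperimentConfig(
            scene=Scene(gamma=0.5, mean_luminance=0.5)
        ),
        "static_edge_gamma09": ExperimentConfig(
            scene=Scene(gamma=0.9, mean_luminance=0.5)
        ),
        "blank_gamma0": ExperimentConfig(
            scene=Scene(gamma=0.0, mean_luminance=0.5),
            engine=EngineConfig(duration=5.0),
        ),
        "bounded_no_object": ExperimentConfig(
            scene=Scene(
                gamma=0.5,
                mean_luminance=0.5,
                field_wrap=FieldWrap.bounded,
                edge_azimuth_deg=90.0,
                screen_center_deg=90.0,
                screen_halfwidth_deg=30.0,
            ),
            engine=EngineConfig(duration=5.0, initial_omega=0.0, initial_n1=0.0),
        ),
        "moving_edge_pursuit": ExperimentConfig(
            scene=Scene(
                gamma=PURSUIT_GAMMA,
                mean_luminance=0.5,
                edge_velocity_deg_s=PURSUIT_EDGE_SPEED,
                motion_half_period_s=PURSUIT_HALF_PERIOD,
            ),
            params=pursuit_params(),
            engine=EngineConfig(duration=32.0),
            analysis=AnalysisConfig(),
        ),
    }
    paths: dict[str, Path] = {}
    for name, cfg in fixtures.items():
        path = out / f"{name}.json"
        save_config(cfg, path)
        paths[name] = path
    return paths
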