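"""Run an experiment described by an :class:`ExperimentConfig`."""

from __future__ import annotations

from .config import ExperimentConfig
from .engine import Trajectory, run_ideal, run_replay, run_sensor
from .percept import LimitCycleSummary, Percept, analyze


def run_experiment(
    cfg: ExperimentConfig,
    replay_trajectory: Trajectory | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Execute the configured run and return its trajectory.

    ``seed`` overrides the config seed (it is forwarded to the engine, from
    which any stochastic stream — currently only sensor event-time jitter —
    is derived).  Replay mode needs either ``replay_trajectory`` or a
    ``replay_source`` path in the config.
    """
    engine = cfg.engine.model_copy(
        update={"seed": cfg.seed if seed is None else seed}
    )
    if cfg.mode == "ideal":
        return run_ideal(cfg.scene.gamma, cfg.params, engine)
    if cfg.mode == "sensor":
        return run_sensor(cfg.scene, cfg.params, cfg.sensor, engine)
    if replay_trajectory is None:
        if cfg.replay_source is None:
            raise ValueError("replay mode needs replay_trajectory or replay_source")
        replay_trajectory = Trajectory.from_csv(cfg.replay_source)
    return run_replay(cfg.scene, replay_trajectory, cfg.params, cfg.sensor, engine)


def analyze_experiment(
    cfg: ExperimentConfig, traj: Trajectory
) -> tuple[LimitCycleSummary, Percept]:
    """Run the percept pipeline with the config's analysis settings."""
    a = cfg.analysis
    return analyze(
        traj,
        cfg.params,
        tolerance=a.residual_tolerance,
        c_d=a.c_d,
        sigma_dyn=a.sigma_dyn,
        sigma_ret=a.sigma_ret,
        refine_decode=a.refine_decode,
    )
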