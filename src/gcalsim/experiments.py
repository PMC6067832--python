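"""Perturbation registry and experiment protocols.

Perturbations are named scalar changes to the resolved configuration (a
projection strength, a learning rate, the gain-control strength or the
homeostatic adaptation rate), applied between training phases.  They never
touch weight arrays, so they are exactly reversible and support the sequential
protocol's mid-run restoration of afferent strengths.

The registry covers the unmodified control (20,000 iterations), the two
best-fitting disease models — *chronic*: 10% reduced V1 lateral inhibition
plus a tripled LGN->V1 learning rate after the pretraining phase; *FES*
(first-episode): 15% reduced retina->LGN and LGN->V1 strengths — the
alternative models B-G, the parameter-class sweeps, and the sequential
FES-then-chronic protocol.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

from . import __version__ as _version
from .config import ConfigurationError, ModelConfig, config_to_dict, get_path, set_path
from .measurement import MeasurementResult, measure_state
from .model import ModelState, build_model
from .plasticity import train

__all__ = [
    "PerturbationSpec",
    "Phase",
    "Protocol",
    "apply_perturbation",
    "invert_perturbation",
    "run_protocol",
    "sequential_protocol",
    "PROTOCOLS",
    "SWEEP_CLASSES",
    "sweep_protocols",
    "CHRONIC_PERTURBATIONS",
    "FES_PERTURBATIONS",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """A named scalar parameter change.

    ``mode='scale'`` multiplies the current value by ``value``; ``mode='set'``
    assigns it.  ``onset_iteration`` records when the change takes effect
    (informational; protocols apply perturbations at phase boundaries).
    """

    parameter: str
    mode: str
    value: float
    onset_iteration: int | None = None

    def __post_init__(self):
        if self.mode not in ("scale", "set"):
            raise ValueError(f"mode must be 'scale' or 'set', got {self.mode!r}")
        if self.mode == "scale" and self.value <= 0:
            raise ValueError("scale perturbation values must be > 0")


def apply_perturbation(state: ModelState, spec: PerturbationSpec) -> dict:
    """Apply a perturbation to the state's config in place.

    Only the named scalar changes; weights, thresholds and traces are
    untouched.  Returns (and logs) an undo record with the prior value.
    """
    old = get_path(state.config, spec.parameter)
    if dataclasses.is_dataclass(old):
        raise ConfigurationError(f"config path {spec.parameter!r} is a section, not a scalar")
    new = old * spec.value if spec.mode == "scale" else spec.value
    set_path(state.config, spec.parameter, new)
    state.config.validate()
    record = {
        "iteration": state.iteration,
        "parameter": spec.parameter,
        "mode": spec.mode,
        "value": spec.value,
        "old": old,
        "new": new,
    }
    state.perturbation_log.append(record)
    return record


def invert_perturbation(state: ModelState, record: dict) -> None:
    """Restore the exact prior value from an undo record."""
    set_path(state.config, record["parameter"], record["old"])
    state.perturbation_log.append(
        {
            "iteration": state.iteration,
            "parameter": record["parameter"],
            "mode": "restore",
            "value": record["old"],
            "old": record["new"],
            "new": record["old"],
        }
    )


@dataclass(frozen=True)
class Phase:
    """One protocol phase: perturb (and/or restore), train, optionally measure."""

    name: str
    iterations: int
    perturbations: tuple = ()
    restore: tuple = ()  # parameter paths reset to their initial resolved values
    measure: bool = False

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("phase iteration counts must be >= 0")


@dataclass(frozen=True)
class Protocol:
    name: str
    phases: tuple


@dataclass
class ResultsBundle:
    """Measurements per checkpoint plus the final state and a run manifest."""

    protocol: str
    seed: int
    checkpoints: dict
    final_state: ModelState
    manifest: dict


# ---------------------------------------------------------------------------
# The registry
# ---------------------------------------------------------------------------

CHRONIC_PERTURBATIONS = (
    PerturbationSpec("v1_lateral_inhibitory.strength", "scale", 0.90),
    PerturbationSpec("lgn_to_v1.learning_rate", "scale", 3.0),
)

FES_PERTURBATIONS = (
    PerturbationSpec("retina_to_lgn.strength", "scale", 0.85),
    PerturbationSpec("lgn_to_v1.strength", "scale", 0.85),
)


def _two_phase(name, perturbations, pretrain, post):
    return Protocol(
        name,
        (
            Phase("pretrain", pretrain),
            Phase("perturbed", post, perturbations=tuple(perturbations), measure=True),
        ),
    )


def unmodified(pretrain: int = 10_000, post: int = 10_000) -> Protocol:
    return Protocol(
        "unmodified",
        (Phase("pretrain", pretrain), Phase("continued", post, measure=True)),
    )


def chronic_best(pretrain: int = 10_000, post: int = 10_000) -> Protocol:
    return _two_phase("chronic_best", CHRONIC_PERTURBATIONS, pretrain, post)


def fes_best(pretrain: int = 10_000, post: int = 10_000) -> Protocol:
    return _two_phase("fes_best", FES_PERTURBATIONS, pretrain, post)


def fes_best_1k(pretrain: int = 10_000, post: int = 1_000) -> Protocol:
    """Acute variant: the FES perturbation expressed within 1,000 iterations."""
    return _two_phase("fes_best_1k", FES_PERTURBATIONS, pretrain, post)


def model_b(pretrain: int = 10_000, post: int = 10_000) -> Protocol:
    return _two_phase(
        "model_b", (PerturbationSpec("v1_lateral_excitatory.strength", "scale", 1.25),), pretrain, post
    )


def model_c(pretrain: int = 10_000, post: int = 10_000) -> Protocol:
    return _two_phase(
        "model_c", (PerturbationSpec("v1_lateral_inhibitory.strength", "scale", 0.75),), pretrain, post
    )


def model_d(pretrain: int = 10_000, post: int = 10_000) -> Protocol:
    return _two_phase(
        "model_d",
        (
            PerturbationSpec("v1_lateral_excitatory.strength", "scale", 1.20),
            PerturbationSpec("v1_lateral_excitatory.learning_rate", "set", 0.01),
        ),
        pretrain,
        post,
    )


def model_e(pretrain: int = 10_000, post: int = 10_000) -> Protocol:
    return _two_phase(
        "model_e",
        (
            PerturbationSpec("v1_lateral_inhibitory.strength", "scale", 0.90),
            PerturbationSpec("v1_lateral_excitatory.learning_rate", "set", 0.01),
        ),
        pretrain,
        post,
    )


def model_f(pretrain: int = 10_000, post: int = 10_000) -> Protocol:
    return _two_phase(
        "model_f", (PerturbationSpec("lgn_to_v1.learning_rate", "set", 0.03),), pretrain, post
    )


def model_g(pretrain: int = 10_000, post: int = 10_000) -> Protocol:
    return _two_phase(
        "model_g",
        FES_PERTURBATIONS + (PerturbationSpec("lgn_to_v1.learning_rate", "set", 0.03),),
        pretrain,
        post,
    )


def sequential(pretrain: int = 10_000, fes_iterations: int = 1_000, chronic_iterations: int = 9_000) -> Protocol:
    """FES episode, medication-like strength restoration, then chronic regime.

    The restoration resets both afferent strengths to their baseline values
    while preserving all learned weights, thresholds and traces.
    """
    return Protocol(
        "sequential",
        (
            Phase("pretrain", pretrain),
            Phase("fes", fes_iterations, perturbations=FES_PERTURBATIONS, measure=True),
            Phase(
                "chronic",
                chronic_iterations,
                perturbations=CHRONIC_PERTURBATIONS,
                restore=("retina_to_lgn.strength", "lgn_to_v1.strength"),
                measure=True,
            ),
        ),
    )


PROTOCOLS = {
    "unmodified": unmodified,
    "chronic_best": chronic_best,
    "fes_best": fes_best,
    "fes_best_1k": fes_best_1k,
    "model_b": model_b,
    "model_c": model_c,
    "model_d": model_d,
    "model_e": model_e,
    "model_f": model_f,
    "model_g": model_g,
    "sequential": sequential,
}

#: Parameter-class sweeps: (parameter path(s), mode, values).
SWEEP_CLASSES = {
    "lateral_excitation_increase": (("v1_lateral_excitatory.strength",), "scale", (1.10, 1.20, 1.25, 1.50)),
    "lateral_inhibition_decrease": (("v1_lateral_inhibitory.strength",), "scale", (0.90, 0.80, 0.75, 0.50)),
    "homeostatic_rate_decrease": (("homeostasis.adaptation_rate",), "scale", (0.50, 0.25, 0.10)),
    "excitatory_learning_rate_increase": (("v1_lateral_excitatory.learning_rate",), "set", (0.01, 0.02, 0.10, 0.20)),
    "gain_control_decrease": (("lgn_gain_control.strength",), "scale", (0.75, 0.50, 0.25)),
    "afferent_decrease": (
        ("retina_to_lgn.strength", "lgn_to_v1.strength"),
        "scale",
        (0.90, 0.85, 0.80, 0.50),
    ),
}


def sweep_protocols(class_name: str, pretrain: int = 10_000, post: int = 10_000) -> list[Protocol]:
    """All protocols of one parameter-class sweep."""
    if class_name not in SWEEP_CLASSES:
        raise KeyError(
            f"unknown sweep class {class_name!r}; valid: {sorted(SWEEP_CLASSES)}"
        )
    paths, mode, values = SWEEP_CLASSES[class_name]
    out = []
    for v in values:
        perts = tuple(PerturbationSpec(p, mode, v) for p in paths)
        out.append(_two_phase(f"{class_name}:{v:g}", perts, pretrain, post))
    return out


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


def run_protocol(
    protocol: Protocol | str,
    seed: int,
    config: ModelConfig | None = None,
    initial_state: ModelState | None = None,
    log_every: int = 100,
    **builder_kwargs,
) -> ResultsBundle:
    """Execute a protocol's phases and measure at every declared checkpoint.

    ``initial_state`` may supply a cached state whose iteration count equals a
    phase-prefix boundary of the protocol (typically the shared unperturbed
    pretraining phase); those phases are skipped, which keeps seed-matched
    comparisons across protocols exact while avoiding retraining.  The cached
    state is copied, never mutated.
    """
    if isinstance(protocol, str):
        if protocol not in PROTOCOLS:
            raise KeyError(f"unknown protocol {protocol!r}; valid: {sorted(PROTOCOLS)}")
        protocol = PROTOCOLS[protocol](**builder_kwargs)

    if initial_state is not None:
        state = initial_state.copy()
        done = state.iteration
    else:
        state = build_model(config, seed)
        done = 0
    # values to which `restore` paths return: the resolved config at entry
    # (caches are unperturbed baselines, so these are the baseline strengths)
    initial_values = {
        path: get_path(state.config, path)
        for phase in protocol.phases
        for path in phase.restore
    }

    checkpoints: dict[str, MeasurementResult] = {}
    elapsed = 0
    for phase in protocol.phases:
        if elapsed + phase.iterations <= done:
            # phase assumed already contained in the cached initial state
            elapsed += phase.iterations
            if elapsed == done and phase.measure:
                checkpoints[phase.name] = measure_state(state, model_id=protocol.name)
            continue
        if elapsed < done:
            raise ValueError(
                f"initial_state.iteration={done} does not align with phase "
                f"boundaries of protocol {protocol.name!r}"
            )
        for path in phase.restore:
            set_path(state.config, path, initial_values[path])
            state.perturbation_log.append(
                {
                    "iteration": state.iteration,
                    "parameter": path,
                    "mode": "restore",
                    "value": initial_values[path],
                    "old": None,
                    "new": initial_values[path],
                }
            )
        for spec in phase.perturbations:
            apply_perturbation(state, replace(spec, onset_iteration=state.iteration))
        train(state, phase.iterations, log_every=log_every)
        elapsed += phase.iterations
        if phase.measure:
            checkpoints[phase.name] = measure_state(state, model_id=protocol.name)

    manifest = {
        "protocol": protocol.name,
        "seed": seed,
        "software_version": _version,
        "phases": [
            {
                "name": p.name,
                "iterations": p.iterations,
                "perturbations": [dataclasses.asdict(s) for s in p.perturbations],
                "restore": list(p.restore),
            }
            for p in protocol.phases
        ],
        "config": config_to_dict(state.config),
        "final_iteration": state.iteration,
    }
    return ResultsBundle(
        protocol=protocol.name,
        seed=seed,
        checkpoints=checkpoints,
        final_state=state,
        manifest=manifest,
    )


def sequential_protocol(
    pretrain_iterations: int = 10_000,
    seed: int = 0,
    config: ModelConfig | None = None,
    initial_state: ModelState | None = None,
    fes_iterations: int = 1_000,
    chronic_iterations: int = 9_000,
) -> ResultsBundle:
    """Run the sequential FES -> restore -> chronic protocol."""
    return run_protocol(
        sequential(pretrain_iterations, fes_iterations, chronic_iterations),
        seed,
        config=config,
        initial_state=initial_state,
    )
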