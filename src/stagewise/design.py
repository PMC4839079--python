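"""Experiment design: samples, stages and stage transitions."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ExperimentDesign:
    """Maps samples to stages and orders stages/transitions.

    Parameters
    ----------
    samples
        Ordered sample identifiers; defines column order of matrices.
    stage_of
        Mapping from sample identifier to its stage label.
    stage_order
        Ordered stage labels (e.g. ``["S1", "S2", "S3"]``).
    transitions
        Ordered ``(from_stage, to_stage)`` pairs; defaults to consecutive
        stage pairs of ``stage_order``.
    """

    samples: tuple[str, ...]
    stage_of: dict[str, str]
    stage_order: tuple[str, ...]
    transitions: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "stage_order", tuple(self.stage_order))
        if not self.transitions:
            trans = tuple(
                (a, b) for a, b in zip(self.stage_order[:-1], self.stage_order[1:])
            )
            object.__setattr__(self, "transitions", trans)
        else:
            object.__setattr__(
                self, "transitions", tuple(tuple(t) for t in self.transitions)
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs in design")
        for s in self.samples:
            if s not in self.stage_of:
                raise ValueError(f"sample {s!r} has no stage assignment")
            if self.stage_of[s] not in self.stage_order:
                raise ValueError(
                    f"sample {s!r} maps to unknown stage {self.stage_of[s]!r}"
                )
        for a, b in self.transitions:
            if a not in self.stage_order or b not in self.stage_order:
                raise ValueError(f"transition ({a!r}, {b!r}) uses unknown stage")

    def samples_of(self, stage: str) -> list[str]:
        """Samples belonging to *stage*, in design order."""
        if stage not in self.stage_order:
            raise KeyError(f"unknown stage {stage!r}")
        return [s for s in self.samples if self.stage_of[s] == stage]

    def transition_label(self, transition: tuple[str, str]) -> str:
        """``T<i>`` label of a transition by its position (1-based)."""
        idx = list(self.transitions).index(tuple(transition))
        return f"T{idx + 1}"

    def require_replicates(self, minimum: int = 2) -> None:
        """Raise if any stage has fewer than *minimum* samples."""
        for stage in self.stage_order:
            n = len(self.samples_of(stage))
            if n < minimum:
                raise ValueError(
                    f"stage {stage!r} has {n} samples, needs >= {minimum}"
                )


def three_stage_design(replicates: int = 3) -> ExperimentDesign:
    """Standard S1/S2/S3 design with *replicates* replicates per stage.

    Sample IDs are ``S1a, S1b, ...`` matching the stage/replicate naming
    convention of triplicated staged experiments.
    """
    stages = ("S1", "S2", "S3")
    letters = "abcdefghijklmnopqrstuvwxyz"
    if replicates > len(letters):
        raise ValueError("too many replicates")
    samples = []
    stage_of = {}
    for stage in stages:
        for i in range(replicates):
            sid = f"{stage}{letters[i]}"
            samples.append(sid)
            stage_of[sid] = stage
    return ExperimentDesign(
        samples=tuple(samples),
        stage_of=stage_of,
        stage_order=stages,
        transitions=(("S1", "S2"), ("S2", "S3")),
    )
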