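"""Task-design parameters for a single dual 2-back block.

A block is an 8-minute run of 145 trials per modality with a fixed
3.330-second trial window. Targets ("mark" trials) are positions whose
stimulus matches the stimulus ``n_back`` trials earlier; lures are
non-target repeats at neighbouring lags that invite false alarms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["BlockSpec", "VISUOSPATIAL_SPEC", "AUDITORY_VERBAL_SPEC", "MODALITIES"]

MODALITIES = ("visuospatial", "auditory_verbal")


@dataclass(frozen=True)
class BlockSpec:
    """Structural parameters of one modality's 2-back stimulus stream.

    Parameters
    ----------
    n_trials : int
        Trials per block (145 in the default design: one stimulus every
        3.330 s for about 8 minutes).
    n_back : int
        Match lag defining a target trial.
    trial_duration : float
        Seconds from stimulus onset to the next onset; responses are only
        valid inside this window, so simulated latencies never exceed it.
    max_targets : int
        Upper bound on target trials per block (40 in the default design).
    lure_rate : float
        Fraction of the block's trials set aside as lures, i.e. non-target
        repeats at lag ``n_back - 1`` or ``n_back + 1``.
    alphabet_size : int
        Number of distinct stimuli: 9 grid positions for the visuospatial
        stream, 11 spoken digits (0-10) for the auditory-verbal stream.
    """

    n_trials: int = 145
    n_back: int = 2
    trial_duration: float = 3.330
    max_targets: int = 40
    lure_rate: float = 0.2
    alphabet_size: int = 9

    def __post_init__(self) -> None:
        if self.n_back < 1:
            raise ValueError("n_back must be >= 1")
        if self.n_trials < self.n_back + 1:
            raise ValueError("n_trials must be >= n_back + 1")
        if not 0 <= self.max_targets <= self.n_trials - self.n_back:
            raise ValueError(
                "max_targets must lie in [0, n_trials - n_back]"
            )
        if not 0.0 <= self.lure_rate <= 1.0:
            raise ValueError("lure_rate must lie in [0, 1]")
        if self.alphabet_size < 3:
            raise ValueError(
                "alphabet_size must be >= 3 so target, lure and filler "
                "stimulus classes can all be realized"
            )
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")

    @property
    def n_lures(self) -> int:
        """Number of lure trials implied by ``lure_rate`` (nearest integer)."""
        return int(round(self.lure_rate * self.n_trials))

    def with_(self, **kwargs) -> "BlockSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


#: Default visuospatial stream: blue square on a 3x3 grid.
VISUOSPATIAL_SPEC = BlockSpec(alphabet_size=9)

#: Default auditory-verbal stream: spoken digits 0-10.
AUDITORY_VERBAL_SPEC = BlockSpec(alphabet_size=11)


def default_spec(modality: str) -> BlockSpec:
    if modality == "visuospatial":
        return VISUOSPATIAL_SPEC
    if modality == "auditory_verbal":
        return AUDITORY_VERBAL_SPEC
    raise ValueError(f"unknown modality: {modality!r}")
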