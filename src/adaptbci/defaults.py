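"""Packaged default configurations.

The derivation/class choices below are the ones the channel/class ranking
sweep identifies for this kind of five-task ERD session: a vertex and two
parietal bipolar derivations with the four classes Feet, Hand, Word, Math
for the Auto configuration, and three sensorimotor derivations with the
two motor-imagery classes for the SMR configuration.  They are defaults,
not constants — any derivation names resolvable on the montage are valid.
"""

from __future__ import annotations

from .engine import AdaptiveConfig
from .montage import ElectrodeGrid, default_montage, parse_derivation
from .preprocessing import RejectionConfig, TrialTiming

AUTO_DERIVATIONS: tuple[str, ...] = ("FCz-CPz", "P1-P2", "CP4-PO4")
SMR_DERIVATIONS: tuple[str, ...] = ("C3-CP3", "FCz-CPz", "CP4-P4")
MINI_DERIVATIONS: tuple[str, ...] = ("FCz-CPz",)

AUTO_CLASSES: tuple[str, ...] = ("Feet", "Hand", "Word", "Math")
SMR_CLASSES: tuple[str, ...] = ("Feet", "Hand")

_MODE_DEFAULTS = {
    "mini": (MINI_DERIVATIONS, SMR_CLASSES),
    "smr": (SMR_DERIVATIONS, SMR_CLASSES),
    "auto": (AUTO_DERIVATIONS, AUTO_CLASSES),
}


def default_config(
    mode: str,
    grid: ElectrodeGrid | None = None,
    derivations: tuple[str, ...] | None = None,
    classes: tuple[str, ...] | None = None,
    timing: TrialTiming | None = None,
    rejection: RejectionConfig | None = None,
    **kwargs,
) -> AdaptiveConfig:
    """An :class:`AdaptiveConfig` with the packaged defaults for a mode."""
    if mode not in _MODE_DEFAULTS:
        raise ValueError(f"unknown mode {mode!r}")
    grid = grid or default_montage()
    d_names, cls = _MODE_DEFAULTS[mode]
    derivations = derivations or d_names
    classes = tuple(classes or cls)
    derivs = tuple(parse_derivation(grid, name) for name in derivations)
    return AdaptiveConfig(
        mode=mode,
        derivations=derivs,
        classes=classes,
        timing=timing or TrialTiming(),
        rejection=rejection or RejectionConfig(),
        **kwargs,
    )
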