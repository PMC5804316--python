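"""Pore-block conversion of IC50 and exposure into fractional block.

A single-site pore-block (Hill coefficient 1) model gives the fraction
of current blocked at the effective free therapeutic plasma
concentration (EFTPC):

    block = 1 / (1 + IC50 / EFTPC)

so a drug at exactly its IC50 blocks half the current.  The result
feeds either the net-block score directly or a biophysical cell model
through conductance scaling g -> g * (1 - block).
"""

from __future__ import annotations

import math

from .datasets_io import BlockProfile, CompoundRecord
from .errors import DomainError


def pore_block(ic50: float, eftpc: float) -> float:
    """Fraction of current blocked at concentration ``eftpc``.

    Parameters
    ----------
    ic50
        Half-maximal inhibitory concentration (µM, > 0).
    eftpc
        Free therapeutic plasma concentration (µM, > 0).

    Returns
    -------
    float
        ``1 / (1 + ic50 / eftpc)``, strictly in (0, 1); decreasing in
        ``ic50``, increasing in ``eftpc``, and invariant to a common
        rescaling of the two concentrations.
    """
    if not (math.isfinite(ic50) and ic50 > 0):
        raise DomainError(f"IC50 must be positive and finite, got {ic50}")
    if not (math.isfinite(eftpc) and eftpc > 0):
        raise DomainError(f"EFTPC must be positive and finite, got {eftpc}")
    return 1.0 / (1.0 + ic50 / eftpc)


def blocks_for_compound(record: CompoundRecord) -> BlockProfile:
    """Apply the pore-block model to every measured channel of a compound.

    Unmeasured channels stay absent from the resulting profile; they are
    not zero-filled here, so downstream consumers can distinguish "not
    measured" from "measured, no block".
    """
    block = {}
    for channel, ic50 in record.ic50.items():
        try:
            block[channel] = pore_block(ic50, record.eftpc)
        except DomainError as err:
            raise DomainError(f"{record.name}: {err}") from err
    return BlockProfile(compound=record.name, block=block)


def scale_conductance(base_conductance: float, block: float) -> float:
    """Scale an ion-channel conductance by the blocked fraction.

    This is the contract by which fractional block enters a biophysical
    cell model: the drugged conductance is ``g * (1 - block)``.
    """
    if not (math.isfinite(block) and 0.0 <= block <= 1.0):
        raise DomainError(f"block must lie in [0, 1], got {block}")
    if not (math.isfinite(base_conductance) and base_conductance >= 0.0):
        raise DomainError(f"conductance must be non-negative, got {base_conductance}")
    return base_conductance * (1.0 - block)
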