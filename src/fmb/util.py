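"""Shared constants, errors and seeding helpers."""

from __future__ import annotations

import numpy as np

#: Fluxes with absolute value below this are treated as zero everywhere
#: (activity calls, flux-pattern ties, knockout checks).
ZERO_TOL = 1e-6

#: Tolerance for calling two reaction rows "exactly the same" (max-norm).
DUPLICATE_TOL = 1e-9


class FMBError(Exception):
    """Base class for package errors."""


class ModelError(FMBError):
    """Malformed or inconsistent metabolic model."""


class ConstraintError(FMBError):
    """Invalid experimental-constraint table."""


class InfeasibleProblemError(FMBError):
    """An LP required by the pipeline has no feasible point."""


def column_rng(master_seed: int, condition_index: int, sample_index: int) -> np.random.Generator:
    """Deterministic per-column generator.

    Seeded with the (master seed, condition, sample) triple so either
    condition's samples can be regenerated independently of the other.
    """
    return np.random.default_rng([int(master_seed), int(condition_index), int(sample_index)])
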