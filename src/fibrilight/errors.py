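"""Exception hierarchy.

Data-format problems, near-resonant denominators and degenerate ensembles
each get a dedicated class so callers (and the CLI exit-code mapping) can
tell user-data errors apart from usage errors.
"""


class FibrilightError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(FibrilightError):
    """A delimited table is missing a required column or is malformed."""


class TableParseError(FibrilightError):
    """A cell could not be parsed; the message names the offending row."""


class DuplicateRecordError(FibrilightError):
    """Two rows share the same (site_id, frame_index) key."""


class UnknownStateError(FibrilightError):
    """A state label is not part of the manifold."""


class ResonanceError(FibrilightError):
    """An SOS energy denominator is too close to zero."""

    def __init__(self, state: str, detuning: float):
        self.state = state
        self.detuning = detuning
        super().__init__(
            f"intermediate state {state!r} is near-resonant with the photon "
            f"energy (detuning {detuning:.3e} hartree)"
        )


class DegenerateEnsembleError(FibrilightError):
    """Too few distinct values to estimate an ensemble width."""


class EmptyWindowError(FibrilightError):
    """No snapshot falls inside the requested averaging window."""
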