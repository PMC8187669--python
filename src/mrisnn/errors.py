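"""Exception hierarchy for the mrisnn package."""


class MrisnnError(Exception):
    """Base class for all package errors."""


class ValidationError(MrisnnError, ValueError):
    """Invalid input data or configuration."""


class PlacementError(MrisnnError):
    """Neuron placement is impossible (e.g. fewer cloud points than channels)."""


class NoConnectionError(MrisnnError, KeyError):
    """A weight was queried for a pair of neurons that are not neighbours."""


class DegenerateStateError(MrisnnError):
    """A normaliser or divisor collapsed to zero during training."""


class NumericalOverflowError(MrisnnError):
    """Neuron state left the finite range during integration."""

    def __init__(self, neuron_ids):
        self.neuron_ids = list(neuron_ids)
        super().__init__(f"non-finite membrane state for neuron id(s) {self.neuron_ids}")


class ContractError(MrisnnError, ValueError):
    """Mismatched shapes/lengths between quantities that must be aligned."""


class FilterDesignError(MrisnnError):
    """Infeasible FIR filter specification."""
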