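"""Exception hierarchy for coilscan."""


class CoilscanError(Exception):
    """Base class for all coilscan errors."""


class SpecError(CoilscanError, ValueError):
    """Malformed or inconsistent fragmentation specification (N_L_O)."""


class SequenceError(CoilscanError, ValueError):
    """Invalid input amino-acid sequence."""


class ModelError(CoilscanError, ValueError):
    """Malformed structural model (PDB) or confidence data (PAE)."""


class IntegrationError(CoilscanError, ValueError):
    """Inconsistency between the division manifest and per-fragment features."""
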