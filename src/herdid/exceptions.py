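"""Exception hierarchy shared across the package.

``ValidationError`` covers bad values and inconsistent configuration,
``ShapeError`` covers dimension mismatches, ``StateError`` covers operations
issued against an object in the wrong state (e.g. matching against an empty
gallery), and ``ConflictError`` covers attempts to re-register an identity.
The command-line layer maps these onto distinct exit codes.
"""


class HerdIdError(Exception):
    """Base class for all package errors."""


class ValidationError(HerdIdError, ValueError):
    """Invalid value, configuration, or input contents."""


class ShapeError(HerdIdError, ValueError):
    """Array dimensions do not line up."""


class StateError(HerdIdError, RuntimeError):
    """Operation not valid in the object's current state."""


class ConflictError(HerdIdError, ValueError):
    """An identity already exists where a new one was being added."""
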