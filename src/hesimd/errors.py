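"""Exception types raised by the packed-vector runtime."""


class HESimdError(Exception):
    """Base class for all package errors."""


class CapacityError(HESimdError):
    """An algorithm's slot-capacity constraint (Ocon) is violated."""


class LevelExhaustedError(HESimdError):
    """A multiplication would exceed the leveled-scheme depth budget."""


class LayoutError(HESimdError):
    """Operands are in an incompatible packing layout (spacing, shape, key)."""


class DecryptionError(HESimdError):
    """Decryption attempted without, or with the wrong, secret key."""
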