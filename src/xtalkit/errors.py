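"""Error taxonomy.

The library classifies every failure into one of four host-level
categories so that embedding applications (scripts, GUIs, visualisation
plugins) never see an unclassified exception escape:

* unrecoverable library failures      -> ``RuntimeError``
* out-of-range element access         -> ``IndexError``
* bad lengths / bad argument values   -> ``ValueError``
* anything else                       -> :class:`UnknownError`

Internal exception types subclass the corresponding built-in, so
``except ValueError`` works naturally; :func:`translate_error` reports
the category of an arbitrary exception and :func:`guard` converts
unclassified failures into :class:`UnknownError` at an API boundary.
"""

from __future__ import annotations

from contextlib import contextmanager

__all__ = [
    "MessageFatal",
    "OutOfRange",
    "LengthError",
    "InvalidArgument",
    "UnknownError",
    "translate_error",
    "guard",
]


class MessageFatal(RuntimeError):
    """An unrecoverable failure inside the library (I/O, broken state)."""


class OutOfRange(IndexError):
    """Access outside the stored extent of a finite container or map."""


class LengthError(ValueError):
    """A container or argument has the wrong length or shape."""


class InvalidArgument(ValueError):
    """An argument value is outside the function's domain."""


class UnknownError(Exception):
    """Catch-all for failures outside the known taxonomy."""


def translate_error(exc: BaseException) -> type:
    """Return the host error category for an exception instance.

    Categories are ``RuntimeError``, ``IndexError``, ``ValueError`` and
    :class:`UnknownError`; any exception that is not already one of the
    first three maps to the catch-all.
    """
    if isinstance(exc, RuntimeError):
        return RuntimeError
    if isinstance(exc, IndexError):
        return IndexError
    if isinstance(exc, ValueError):
        return ValueError
    return UnknownError


@contextmanager
def guard():
    """Re-raise unclassified exceptions as :class:`UnknownError`.

    Wrap calls made on behalf of a host session: classified errors pass
    through unchanged; anything else surfaces as the catch-all category
    instead of terminating the session with an unexpected type.
    """
    try:
        yield
    except (RuntimeError, IndexError, ValueError, UnknownError):
        raise
    except KeyboardInterrupt:
        raise
    except BaseException as exc:  # noqa: BLE001 - the catch-all IS the contract
        raise UnknownError(f"{type(exc).__name__}: {exc}") from exc
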