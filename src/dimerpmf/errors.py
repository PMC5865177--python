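"""Exception hierarchy.

All package errors derive from :class:`DimerPMFError` so callers can catch
one base class; subclasses mirror the failure modes of each stage
(domain violations, integrator blow-up, WHAM support gaps, ...).
"""


class DimerPMFError(Exception):
    """Base class for all dimerpmf errors."""


class DomainError(DimerPMFError, ValueError):
    """A coordinate lies outside the landscape domain."""


class ConfigError(DimerPMFError, ValueError):
    """Invalid run configuration (spacing, tau_ex, missing keys, ...)."""


class InstabilityError(DimerPMFError, RuntimeError):
    """Integrator step size too large for the sampled forces."""


class QuadratureError(DimerPMFError, RuntimeError):
    """Adaptive quadrature for the marginal free energy failed to converge."""


class PackingError(DimerPMFError, ValueError):
    """Requested assembly snapshot cannot be placed without overlap."""


class ConnectivityError(DimerPMFError, RuntimeError):
    """Umbrella histograms do not form a connected chain of overlaps."""


class NonConvergenceError(DimerPMFError, RuntimeError):
    """Self-consistent iteration hit max_iter before reaching tolerance."""


class ResamplingError(DimerPMFError, ValueError):
    """A window is too short to be split into bootstrap blocks."""


class FormatError(DimerPMFError, ValueError):
    """Malformed input file (missing columns, bad values)."""


class IntegrityError(DimerPMFError, RuntimeError):
    """Internal bookkeeping inconsistency (exchange log vs. series)."""


class EmptySeriesError(FormatError):
    """A series file contained comments/legends but no data rows."""


class EmptySelectionError(DimerPMFError, ValueError):
    """A species/atom selection matched nothing."""


class MetricError(DimerPMFError, ValueError):
    """Conformations are not comparable (bead-count mismatch)."""


class GeometryError(DimerPMFError, ValueError):
    """Degenerate geometry (zero-length reference axis, ...)."""


class LookupError_(DimerPMFError, KeyError):
    """A requested conditioning value has no matching umbrella window."""
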