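"""Exception hierarchy.

All voxsbml errors derive from :class:`VoxSBMLError` so callers can catch the
package's failures with a single except clause; subclasses distinguish bad user
input from internal inconsistencies.
"""


class VoxSBMLError(Exception):
    """Base class for all voxsbml errors."""


class InputError(VoxSBMLError):
    """A caller-supplied value (file, mask, identifier, expression) is invalid."""


class HierarchyError(VoxSBMLError):
    """Two masks partially overlap with neither containing the other, so no
    containment hierarchy exists."""


class CapacityError(VoxSBMLError):
    """More volume domain types than distinct 8-bit sampled values allow."""


class SBMLImportError(InputError):
    """A document cannot be imported (wrong level/version, missing spatial
    package, malformed XML, undecodable sampled field)."""


class ExportRefusedError(VoxSBMLError):
    """Export was refused because validation reported error-severity issues.

    The offending issues are attached as :attr:`issues`.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        lines = "; ".join(str(i) for i in self.issues)
        super().__init__(f"model failed validation ({len(self.issues)} issue(s)): {lines}")
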