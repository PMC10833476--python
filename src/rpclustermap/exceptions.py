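"""Exception hierarchy shared across the package."""


class RPClusterMapError(Exception):
    """Base class for all package errors."""


class RegistryError(RPClusterMapError):
    """Unknown gene, model, or variant requested from the cluster registry."""


class FormatError(RPClusterMapError):
    """Malformed annotation input (feature table, GFF3, GenBank, report)."""


class InputError(RPClusterMapError):
    """Invalid argument values (sequences, thresholds, duplicate ids)."""


class TemplateError(RPClusterMapError):
    """Unknown synthetic template or invalid perturbation spec."""
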