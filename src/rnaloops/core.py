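"""Shared vocabulary: biotypes, edge classes and package exceptions.

The pipeline works on a heterogeneous directed regulatory network whose
nodes carry exactly one of four biotypes (TF, miRNA, lncRNA, mRNA) and
whose edges fall into a small number of regulator->target classes.
Everything else in the package imports these names from here.
"""

from __future__ import annotations

TF = "TF"
MIRNA = "miRNA"
LNCRNA = "lncRNA"
MRNA = "mRNA"

BIOTYPES = (TF, MIRNA, LNCRNA, MRNA)

#: edge classes as they appear in association tables, keyed by the
#: (source biotype, target biotype) they declare.  miRNA->TF edges are not a
#: table class: they arise from miRNA->mRNA records whose target is a
#: registered TF and are relabeled during interactome assembly.
EDGE_CLASSES = {
    "tf_mrna": (TF, MRNA),
    "tf_lncrna": (TF, LNCRNA),
    "tf_mirna": (TF, MIRNA),
    "mirna_mrna": (MIRNA, MRNA),
    "mirna_lncrna": (MIRNA, LNCRNA),
}

FFL_TYPES = ("tf_mediated", "mirna_mediated", "mixed")

UP = "up"
DOWN = "down"

STIMULATORY = "stimulatory"
INHIBITORY = "inhibitory"
UNSIGNED = "unsigned"


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class ParseError(ValueError):
    """Malformed input file; the message carries line-level detail."""


class BiotypeConflictError(ValueError):
    """The same identifier was declared with incompatible biotypes."""


class AmbiguityError(ValueError):
    """Duplicate records where exactly one was expected."""


class DegenerateInputError(ValueError):
    """Input on which the requested statistic is undefined."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""
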