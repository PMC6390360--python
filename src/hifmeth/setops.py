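"""Directional set algebra over differential contrasts.

Crossing two filtered gene sets yields three lists — genes exclusive to
either contrast and genes common to both — and the common genes are then
split by the sign of their two fold changes into concordant (same
regulation in both contrasts) and discordant (opposite regulation).
Under the HIF1A-silencing design, common genes of the two silencing
contrasts are "HIF1A target genes"; under the hypoxia design, concordant
common genes are "Hypoxia targets" (oxygen-driven, HIF1A-agnostic) and
discordant ones are "HIF1A direct-targets" (their hypoxia response
inverts when HIF1A is depleted).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CrossClassification, DirectionalGeneSet

HIF1A_SCHEME_LABELS = {
    "exclusive_a": "exclusively in normoxia",
    "exclusive_b": "exclusively in hypoxia",
    "common": "HIF1A target genes",
}
HYPOXIA_SCHEME_LABELS = {
    "concordant": "Hypoxia targets",
    "discordant": "HIF1A direct-targets",
}


def cross_contrasts(
    a: DirectionalGeneSet, b: DirectionalGeneSet
) -> CrossClassification:
    """Partition genes of two contrasts into exclusive-A/exclusive-B/common.

    Common genes carry both contrasts' fold changes so concordance can be
    classified afterwards.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both directional sets must be nonempty")
    genes_a, genes_b = a.genes, b.genes
    common_genes = sorted(genes_a & genes_b)
    common = pd.DataFrame(
        {
            "log2fc_a": a.entries.loc[common_genes, "log2fc"].to_numpy(),
            "log2fc_b": b.entries.loc[common_genes, "log2fc"].to_numpy(),
        },
        index=pd.Index(common_genes, name="gene_id"),
    )
    return CrossClassification(
        label_a=a.contrast_label,
        label_b=b.contrast_label,
        exclusive_a=sorted(genes_a - genes_b),
        exclusive_b=sorted(genes_b - genes_a),
        common=common,
    )


def classify_concordance(cross: CrossClassification) -> CrossClassification:
    """Split common genes by fold-change sign agreement.

    Concordant: same sign in both contrasts; discordant: opposite signs.
    Genes with a zero fold change in either contrast (possible only on
    unfiltered inputs) are reported separately in ``zero_sign`` and belong
    to neither class.
    """
    if cross.common is None:
        raise ValueError("cross has no common table")
    if cross.common[["log2fc_a", "log2fc_b"]].isna().any().any():
        raise ValueError("common genes missing a fold change")
    sign_a = np.sign(cross.common["log2fc_a"].to_numpy())
    sign_b = np.sign(cross.common["log2fc_b"].to_numpy())
    zero = (sign_a == 0) | (sign_b == 0)
    cross.concordant = sorted(cross.common.index[(sign_a == sign_b) & ~zero])
    cross.discordant = sorted(cross.common.index[(sign_a != sign_b) & ~zero])
    cross.zero_sign = sorted(cross.common.index[zero])
    return cross


def name_partitions(
    cross: CrossClassification, scheme: str
) -> dict[str, list[str]]:
    """Label the partition lists under a naming scheme.

    ``hif1a_scheme`` names the exclusive/common lists of the two
    HIF1A-silencing contrasts; ``hypoxia_scheme`` names the
    concordant/discordant split of the common genes.
    """
    if scheme == "hif1a_scheme":
        return {
            HIF1A_SCHEME_LABELS["exclusive_a"]: list(cross.exclusive_a),
            HIF1A_SCHEME_LABELS["exclusive_b"]: list(cross.exclusive_b),
            HIF1A_SCHEME_LABELS["common"]: cross.common_genes,
        }
    if scheme == "hypoxia_scheme":
        if cross.concordant is None or cross.discordant is None:
            raise ValueError("cross must be concordance-classified first")
        return {
            HYPOXIA_SCHEME_LABELS["concordant"]: list(cross.concordant),
            HYPOXIA_SCHEME_LABELS["discordant"]: list(cross.discordant),
        }
    raise ValueError(f"unknown scheme {scheme!r}")
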