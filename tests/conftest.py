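import numpy as np
import pytest

from afmissense.variants import (
    ProteinChange,
    Significance,
    Source,
    VariantClass,
    VariantRecord,
)


def make_record(
    position=101,
    wt="H",
    mut="Q",
    gene="CLIC2",
    uniprot="O15247",
    significance=Significance.PATHOGENIC,
    stars=2,
    condition="Hereditary cancer syndrome",
    source=Source.CLINVAR,
    maf=None,
):
    """A well-formed missense record passing all default filters."""
    change = ProteinChange(wildtype_aa=wt, position=position, mutant_aa=mut)
    return VariantRecord(
        gene_symbol=gene,
        uniprot_id=uniprot,
        change=change,
        clinical_significance=significance,
        review_stars=stars,
        condition_text=condition,
        source=source,
        variant_class=VariantClass.MISSENSE,
        change_text=str(change),
        maf=maf,
    )


def make_truncating(position=500, **kwargs):
    """A truncating (stop-gain) record passing the non-class filters."""
    base = make_record(position=position, **kwargs)
    return VariantRecord(
        gene_symbol=base.gene_symbol,
        uniprot_id=base.uniprot_id,
        change=None,
        clinical_significance=base.clinical_significance,
        review_stars=base.review_stars,
        condition_text=base.condition_text,
        source=base.source,
        variant_class=VariantClass.TRUNCATING,
        change_text=f"p.Arg{position}Ter",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
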