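import pytest

from pyromux import Panel, SNPDef, DispensationOrder, quadruplex_panel, quintuplex_panel


@pytest.fixture(scope="session")
def quad_panel():
    return quadruplex_panel()


@pytest.fixture(scope="session")
def quint_panel():
    return quintuplex_panel()


def make_snp(snp_id, uns_ref, uns_alt, ploidy=2, maf=0.3, as_read=True,
             orientation="forward"):
    """Toy bi-allelic SNP; alleles named after the variant-position bases."""
    i = next(k for k, (a, b) in enumerate(zip(uns_ref, uns_alt)) if a != b)
    return SNPDef(
        snp_id=snp_id, chromosome="1",
        allele_ref=uns_ref[i], allele_alt=uns_alt[i],
        uns_ref=uns_ref, uns_alt=uns_alt,
        orientation=orientation, as_read=as_read, ploidy=ploidy, maf=maf,
    )


def make_panel(order, *snps, name="toy"):
    return Panel(name=name, snps=tuple(snps), order=DispensationOrder(order))
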