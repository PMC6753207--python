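import numpy as np
import pytest

from tsmr.harmonize import HarmonizedInstrument
from tsmr.io import InstrumentTable, SnpAssociation


def make_snp(rsid, beta=0.1, se=0.01, pvalue=1e-10, ea="A", oa="G",
             chrom="1", pos=1000) -> SnpAssociation:
    return SnpAssociation(
        rsid=rsid, chromosome=chrom, position=pos, effect_allele=ea,
        other_allele=oa, beta=beta, se=se, pvalue=pvalue,
    )


def make_harmonized(rsid, beta_x, beta_y, se_y, se_x=0.01, cancer_type="test",
                    smoking_related=False) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        rsid=rsid, effect_allele="A", other_allele="G",
        beta_exposure=beta_x, se_exposure=se_x, beta_outcome=beta_y,
        se_outcome=se_y, cancer_type=cancer_type, smoking_related=smoking_related,
    )


def random_harmonized(rng: np.random.Generator, n: int, theta: float = 0.0,
                      cancer_type: str = "test") -> list[HarmonizedInstrument]:
    """Random harmonized set with heteroscedastic outcome SEs."""
    beta_x = rng.uniform(0.05, 0.5, n) * rng.choice([-1, 1], n)
    se_y = rng.uniform(0.005, 0.05, n)
    beta_y = theta * beta_x + rng.normal(0, se_y)
    return [
        make_harmonized(f"rs{i:06d}", beta_x[i], beta_y[i], se_y[i],
                        cancer_type=cancer_type)
        for i in range(n)
    ]


@pytest.fixture
def lung_like_table() -> InstrumentTable:
    """18 genome-wide significant instruments, the lung-cancer group size."""
    rng = np.random.default_rng(42)
    records = [
        make_snp(
            f"rs{i:06d}",
            beta=float(rng.uniform(0.05, 0.3) * rng.choice([-1, 1])),
            se=0.01,
            pvalue=float(rng.uniform(1e-30, 1e-9)),
            chrom=str(i % 22 + 1),
            pos=1000 + i,
        )
        for i in range(18)
    ]
    return InstrumentTable(cancer_type="lung", smoking_related=True, records=records)
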