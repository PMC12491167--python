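import numpy as np
import pytest
from hypothesis import settings

from medmr.sumstats import HarmonizedPair, SummaryRecord

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                beta=0.1, se=0.01, pvalue=1e-8, n=50_000) -> SummaryRecord:
    return SummaryRecord(snp_id, chrom, pos, ea, oa, eaf, beta, se, pvalue, n)


def make_pair(snp_id="rs1", chrom="1", pos=1000, beta_exp=0.1, beta_out=0.05,
              se_exp=0.005, se_out=0.01, pval_exp=1e-8, pval_out=0.5,
              eaf=0.3, n_exp=50_000, n_out=50_000, ea="A", oa="G") -> HarmonizedPair:
    return HarmonizedPair(snp_id, chrom, pos, ea, oa, beta_exp, se_exp, pval_exp,
                          eaf, n_exp, beta_out, se_out, pval_out, n_out)


def pairs_from_ratios(ratios, beta_exp=0.1, se_out=0.01, **kw):
    """One pair per ratio, constant exposure beta => equal IVW ratio weights."""
    return [make_pair(snp_id=f"rs{i+1}", pos=(i + 1) * 10_000,
                      beta_exp=beta_exp, beta_out=beta_exp * r, se_out=se_out, **kw)
            for i, r in enumerate(ratios)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sumstats_file(tmp_path):
    """Write records (or raw rows) to a TSV and return the path."""
    def _write(rows, header=None, name="sumstats.tsv"):
        path = tmp_path / name
        if header is None:
            header = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                      "eaf", "beta", "se", "pvalue", "n"]
        lines = ["\t".join(header)]
        for r in rows:
            if isinstance(r, SummaryRecord):
                r = [r.snp_id, r.chrom, r.pos, r.effect_allele, r.other_allele,
                     r.eaf, r.beta, r.se, r.pvalue, r.n]
            lines.append("\t".join(str(x) for x in r))
        path.write_text("\n".join(lines) + "\n")
        return path
    return _write
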