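import numpy as np
import pytest

from vafphase.model import VariantSite

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "{contigs}"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
    '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
)


def write_vcf(path, rows, sample="S1", contigs=("1", "2")):
    """Write a minimal single-sample VCF.

    ``rows``: (chrom, pos, ref, alt, gt, (ad_ref, ad_alt)) or with an extra
    trailing ps value for phased genotypes.
    """
    contig_lines = "".join(f"##contig=<ID={c}>\n" for c in contigs)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contigs=contig_lines, sample=sample))
        for row in rows:
            chrom, pos, ref, alt, gt, ad = row[:6]
            ps = row[6] if len(row) > 6 else None
            fmt, val = "GT:AD", f"{gt}:{ad[0]},{ad[1]}"
            if ps is not None:
                fmt, val = "GT:AD:PS", f"{val}:{ps}"
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\t{fmt}\t{val}\n")
    return path


@pytest.fixture
def vcf_writer(tmp_path):
    def _write(name, rows, **kw):
        return str(write_vcf(tmp_path / name, rows, **kw))

    return _write


def make_site(chrom="1", pos=100, n_ref=25, n_alt=25, t_ref=25, t_alt=25, **kw):
    return VariantSite(chrom=chrom, pos=pos, ref="A", alt="G",
                       n_ref=n_ref, n_alt=n_alt, t_ref=t_ref, t_alt=t_alt, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
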