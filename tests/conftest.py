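import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from germlinekit import synthetic


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One default paired synthetic study, generated once and written to disk."""
    outdir = tmp_path_factory.mktemp("study")
    objects = synthetic.generate_study(11, outdir)
    objects["dir"] = outdir
    return objects


@pytest.fixture(scope="session")
def reference_table(study):
    return synthetic.reference_table_from_frame(
        study["reference"], study["discovery"].config.reference_an
    )


def write_vcf(path, body_lines, samples=("s1", "s2", "s3")):
    """Write a minimal VCF with the given body lines."""
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Strand bias">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        "##contig=<ID=1>",
        "##contig=<ID=2>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    Path(path).write_text("\n".join(header + list(body_lines)) + "\n")
    return path
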