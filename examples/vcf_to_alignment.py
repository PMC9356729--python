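"""Convert VCF diploid genotypes into a GT16 alignment.

Writes a tiny VCF, converts it (phased ``A|C`` → AC, unphased ``A/C`` →
the ambiguity {AC, CA}, ``./.`` → missing), and shows the resulting
internal codes and FASTA dialect.
"""

import tempfile
from pathlib import Path

from errophylo.io import vcf_to_gt16, write_fasta

VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tcell1\tcell2
chr1\t101\t.\tA\tC\t.\t.\t.\tGT\t0|1\t1/0
chr1\t202\t.\tG\tT\t.\t.\t.\tGT\t1|1\t./.
chr1\t303\t.\tC\tA,G\t.\t.\t.\tGT\t1|2\t0|0
"""

with tempfile.TemporaryDirectory() as d:
    vcf_path = Path(d) / "calls.vcf"
    vcf_path.write_text(VCF)
    aln = vcf_to_gt16(vcf_path)
    print(f"{aln.n_cells} cells x {aln.n_sites} sites; "
          f"phased={aln.phased}; positions={aln.positions}")
    for cell in aln.cells:
        print(f"  {cell}: {aln.code_strings(cell)}")
    fasta = Path(d) / "calls.fasta"
    write_fasta(aln, fasta)
    print("\nFASTA dialect (two characters per site, lowercase = unphased "
          "heterozygote, ?? = missing):")
    print(fasta.read_text())
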