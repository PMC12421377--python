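import textwrap

import pytest


@pytest.fixture
def mini_annotation(tmp_path):
    """Hand-countable three-transcript fixture.

    T1 (+): one AAUAAA.  T2 (+): AAUAAA then AUUAAA.  T3 (-): one AACAAA,
    planted as its reverse complement TTTGTT on the plus genomic strand.
    Returns (gff3_path, fasta_path).
    """
    #            1         2         3         4         5         6
    #   123456789012345678901234567890123456789012345678901234567890
    # T1 spans 1-20 with AATAAA at 6-11
    # T2 spans 21-50 with AATAAA at 26-31 and ATTAAA at 38-43
    # T3 (-) spans 51-70 with TTTGTT at 58-63 (revcomp -> AACAAA)
    seq = (
        "CCGGG" "AATAAA" "CCCGGGCCC"                      # 1-20: T1
        "GGCCC" "AATAAA" "CCGGCC" "ATTAAA" "CCCGGGC"      # 21-50: T2
        "CGGCCGG" "TTTGTT" "CGGCCGG"                      # 51-70: T3
    )
    assert len(seq) == 70
    fasta = tmp_path / "mini.fasta"
    fasta.write_text(">chr1 mini fixture\n" + seq + "\n")
    gff = tmp_path / "mini.gff3"
    gff.write_text(textwrap.dedent("""\
        ##gff-version 3
        chr1\ttest\tmRNA\t1\t20\t.\t+\t.\tID=T1
        chr1\ttest\tmRNA\t21\t50\t.\t+\t.\tID=T2
        chr1\ttest\tmRNA\t51\t70\t.\t-\t.\tID=T3
        chr1\ttest\tregulatory_region\t6\t11\t.\t+\t.\tID=p1;Parent=T1;regulatory_class=polyA_signal_sequence
        chr1\ttest\tregulatory_region\t26\t31\t.\t+\t.\tID=p2;Parent=T2;regulatory_class=polyA_signal_sequence
        chr1\ttest\tregulatory_region\t38\t43\t.\t+\t.\tID=p3;Parent=T2;regulatory_class=polyA_signal_sequence
        chr1\ttest\tregulatory_region\t58\t63\t.\t-\t.\tID=p4;Parent=T3;regulatory_class=polyA_signal_sequence
        """))
    return gff, fasta
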