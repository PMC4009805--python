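"""Remove a 3' adapter from a handful of reads and show what was cut.

An adapter fragment appears at the 3' end of a read whenever the
sequenced fragment is shorter than the read length.  Overlap alignment
finds the adapter (even as a short terminal fragment) and RIGHT-mode
trimming removes everything from the match to the 3' end.
"""

from flexitrim import (
    AlignmentAcceptance,
    ScoringScheme,
    SequenceRecord,
    TagSequence,
    TrimMode,
    apply_trim,
    find_best_tag,
)

ADAPTER = "AGATCGGAAGAGC"  # Illumina TruSeq adapter prefix

reads = [
    # full adapter after a short insert
    SequenceRecord("short_insert", "ACGTACGTACGTACGTACGT" + ADAPTER),
    # only the first 5 adapter bases fit on the read
    SequenceRecord("readthrough", "TTGACCATTGACCATTGACCATTGACCA" + ADAPTER[:5]),
    # no adapter at all
    SequenceRecord("clean", "GATTACAGATTACAGATTACAGATTACA"),
]

tag = TagSequence("truseq", ADAPTER)
scoring = ScoringScheme(1, -1, -6)
acceptance = AlignmentAcceptance(min_overlap=3, threshold=1.0)

for read in reads:
    match = find_best_tag(read, [tag], TrimMode.RIGHT, scoring, acceptance)
    if match is None:
        print(f"{read.id:>13}: no adapter  -> kept {len(read)} nt unchanged")
        continue
    trimmed = apply_trim(read, match)
    aln = match.alignment
    print(
        f"{read.id:>13}: adapter at [{aln.read_start},{aln.read_end}) "
        f"score {aln.score} ({aln.cigar})  -> kept {len(trimmed)} nt"
    )

# The score column shows how much adapter evidence each read carried:
# a full-length perfect hit scores len(adapter), a 5-nt terminal
# fragment only 5 — both above the 3-nt minimum overlap.
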