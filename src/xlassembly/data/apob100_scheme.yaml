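# Packaged apoB-100 segmentation: five subunits, eleven domains, two long
# coils, in full preproprotein numbering (mature protein spans 28-4563).
# The coverage mask excludes residues 2551-2590, which the subunit IV model
# leaves unmodeled.
name: apoB-100
sequence_span: [28, 4563]
segments:
  - {name: "Subunit I",   level: subunit, ranges: [[28, 1017]]}
  - {name: "Subunit II",  level: subunit, ranges: [[1018, 2072]]}
  - {name: "Subunit III", level: subunit, ranges: [[2073, 2550]]}
  - {name: "Subunit IV",  level: subunit, ranges: [[2551, 4057]]}
  - {name: "Subunit V",   level: subunit, ranges: [[4058, 4563]]}
  - {name: "SI domain 1",  level: domain, ranges: [[28, 320]]}
  - {name: "SI domain 2",  level: domain, ranges: [[321, 616]]}
  - {name: "SI domain 3",  level: domain, ranges: [[617, 1017]]}
  - {name: "SII domain 1", level: domain, ranges: [[1501, 2072]]}
  - {name: "SIII domain 1", level: domain, ranges: [[2073, 2273]]}
  - {name: "SIII domain 2", level: domain, ranges: [[2293, 2550]]}
  - {name: "SIV domain 1", level: domain, ranges: [[2929, 3340]]}
  - {name: "SIV domain 2", level: domain, ranges: [[3380, 3717]]}
  - {name: "SIV domain 3", level: domain, ranges: [[2901, 2928], [3341, 3379], [3718, 4057]]}
  - {name: "SV domain 1",  level: domain, ranges: [[4058, 4269]]}
  - {name: "SV domain 2",  level: domain, ranges: [[4270, 4563]]}
  - {name: "SII coil", level: coil, ranges: [[1018, 1500]]}
  - {name: "SIV coil", level: coil, ranges: [[2551, 2900]]}
coverage_mask_excludes:
  - [2551, 2590]
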