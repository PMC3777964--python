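# Packaged fixtures

* `reporter_inserts.fasta` — the five dual-reporter insert sequences of the
  PaYIP3 frameshift study system, verbatim (Podo-1 is the natural -1
  cassette; Podo0 adds one 5' G to restore frame; the IBV hybrids carry the
  T TTA AAC slippery site with 6-nt or 2-nt spacers, and IBV-Podo0 is the
  out-of-frame IBV control).
* `yip3_tree.nwk` / `yip3_states.tsv` — class-level Eumycota species tree
  with the 3'-ORF presence character.  Placements transcribed from the
  published figure at class/order resolution.  Ambiguities: the figure does
  not resolve the branching order among Sordariomycetes+Leotiomycetes,
  Dothideomycetes and Eurotiomycetes with certainty, and Cladosporium
  fulvum stands in for the additional Capnodiales sampled; neither choice
  affects the parsimony mapping (a single gain above the Orbiliomycetes
  split, a single loss in Ascosphaera apis), which depends only on
  Orbiliomycetes being the earliest-diverging Pezizomycotina class and
  A. apis being nested among extension-bearing taxa.
* `reporter_calibration.json` — true efficiencies for the reporter
  simulator, matching the published measurements for the Podo-1 (1%) and
  IBV-Podo0 (0.3%) constructs.
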