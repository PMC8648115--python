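# Default core-promoter element models.
#
# Consensus sequences and TSS-relative scan windows are transcribed from
# the core-promoter literature (Ohler et al. 2002 Drosophila motifs;
# TATA/DPE/MTE/pause-button definitions from the Kadonaga laboratory;
# TCT from Parry et al. 2010; DRE from Hirose et al. 1993).  Offset 0 is
# the TSS base; windows bound where a match may START.  For a faithful
# comparison against any particular study, replace these entries with
# that study's own motif models and windows — set `source: placeholder`
# on any slot awaiting a concrete model and the loader will refuse to
# run until it is filled in.
motifs:
  - name: TATA
    mode: consensus
    model: STATAWAAR
    window_start: -33
    window_end: -25
    source: literature
  - name: DPE_O            # Ohler-style DPE variant
    mode: consensus
    model: KCGGTTSK
    window_start: 23
    window_end: 28
    source: literature
  - name: DPE_K            # Kadonaga-style DPE variant
    mode: consensus
    model: RGWYVT
    window_start: 26
    window_end: 29
    source: literature
  - name: MTE
    mode: consensus
    model: CSARCSSAACGS
    window_start: 17
    window_end: 19
    source: literature
  - name: PB               # pause button
    mode: consensus
    model: KCGRWCG
    window_start: 25
    window_end: 32
    source: literature
  - name: TCT
    mode: consensus
    model: YYCTTTYY
    window_start: -2
    window_end: 0
    source: literature
  - name: DRE
    mode: consensus
    model: WATCGATW
    window_start: -100
    window_end: -1
    source: literature
  - name: Ohler1
    mode: consensus
    model: MYGGTCACACTR
    window_start: -60
    window_end: 1
    source: literature
  - name: Ohler6
    mode: consensus
    model: KTYRGTATWTTT
    window_start: -60
    window_end: 1
    source: literature
  - name: Ohler7
    mode: consensus
    model: KNNCAKCNCTRNY
    window_start: -60
    window_end: 1
    source: literature
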