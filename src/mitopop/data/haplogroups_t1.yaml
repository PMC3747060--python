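# Diagnostic-site definitions for the bovine mitochondrial T1 haplogroup
# system. Positions are 1-based BRS coordinates; "Ts" means a transition
# relative to the reference base at that position, and "A>T" an explicit
# substitution. The root T carries the reference state (empty motif).
#
# Only the motifs for T1, T1b, T1b1, T1c and the 14523-transversion group
# below T1b1 are authoritative here. The motifs for T1a, T1d, T1e and T1f
# are PLACEHOLDERS (marked placeholder: true): the classifier engine is
# correct for any supplied tree, and users working with real data should
# substitute the published defining mutations for those subhaplogroups.
haplogroups:
  - name: T
    parent: null
    motif: []
  - name: T1
    parent: T
    motif:
      - {position: 16050, change: Ts}
      - {position: 16113, change: Ts}
      - {position: 16255, change: Ts}
  - name: T1a
    parent: T1
    motif:
      - {position: 5001, change: Ts, placeholder: true}
  - name: T1b
    parent: T1
    motif:
      - {position: 7542, change: Ts}
  - name: T1c
    parent: T1
    motif:
      - {position: 16122, change: Ts}
  - name: T1d
    parent: T1
    motif:
      - {position: 9001, change: Ts, placeholder: true}
  - name: T1e
    parent: T1
    motif:
      - {position: 11001, change: Ts, placeholder: true}
  - name: T1f
    parent: T1
    motif:
      - {position: 13001, change: Ts, placeholder: true}
  - name: T1b1
    parent: T1b
    motif:
      - {position: 16022, change: Ts}
  - name: T1b1-14523T
    parent: T1b1
    motif:
      - {position: 14523, change: A>T}
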