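# Haplogroup N1a subclade definitions.
#
# Each clade lists the diagnostic mutations arising on the branch from its
# parent, in motif notation per segment (hvs1 positions minus 16000).  An "@"
# prefix marks an expected back mutation (the branch reverts an ancestral
# mutation to the reference state); "anti_hvs1" lists sites whose presence
# excludes the clade outright.
#
# The nested N1a tree: 16147G/16172/16223/16248/16355 basal; N1a1 carries the
# 16147 G->A change plus coding 3336; 16320 characterises all of N1a1a;
# N1a1a1 adds coding 8164, 9300 and back mutation @2702; N1a1a1a adds 16189
# and coding 6641; N1a1a2 adds 16086 with HVS-II 152-199-204-207 and a
# back-mutated 16172; N1a1a3 adds 16154; N1a1b is the N1a1 branch lacking
# 16320.
root: N
clades:
  N1a:
    parent: N
    hvs1: [147G, 172, 223, 248, 355]
  N1a1:
    parent: N1a
    hvs1: [147A]
    coding: [3336]
  N1a1a:
    parent: N1a1
    hvs1: [320]
  N1a1a1:
    parent: N1a1a
    coding: [8164, 9300, "@2702"]
  N1a1a1a:
    parent: N1a1a1
    hvs1: [189]
    coding: [6641]
  N1a1a2:
    parent: N1a1a
    hvs1: [86, "@172"]
    hvs2: [152, 199, 204, 207]
  N1a1a3:
    parent: N1a1a
    hvs1: [154]
  N1a1b:
    parent: N1a1
    anti_hvs1: [320]
# HVS-II mutations implicit at the root of the sampled tree (every published
# record carries 73 and 263).
root_hvs2: [73, 263]
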