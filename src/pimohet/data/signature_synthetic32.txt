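# Synthetic stand-in signature (32 genes).
# These are the signature gene ids planted by the default pimohet synthetic
# cohort generator, NOT a published gene list. Replace this file with your
# own one-gene-per-line list to score a real signature.
g0001
g0002
g0003
g0004
g0005
g0006
g0007
g0008
g0009
g0010
g0011
g0012
g0013
g0014
g0015
g0016
g0017
g0018
g0019
g0020
g0021
g0022
g0023
g0024
g0025
g0026
g0027
g0028
g0029
g0030
g0031
g0032
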