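>TS2 synthetic mt-tRNA cloverleaf (designed fixture)
CACTGTTGTTTACGGGTATGTACAACCCGTATCAGAGGGAAACTATCCCTCAACAGTGT
(((((((.....(((((.......))))).....(((((.......)))))))))))).
AAAAAAAVVVVVCCCCCLLLLLLLCCCCCVVVVVTTTTTLLLLLLLTTTTTAAAAAAAV
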