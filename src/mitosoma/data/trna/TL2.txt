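>TL2 synthetic mt-tRNA cloverleaf (designed fixture)
CTTAGCGTAAAGCAAACTTTATACCGCTTACTACGGTAGCTACGCTCTATTCAAGCGTCGCTAAGC
(((((((.((((....)))).(((((.......)))))...(((((.......)))))))))))).
AAAAAAAVDDDDLLLLDDDDVCCCCCLLLLLLLCCCCCVVVTTTTTLLLLLLLTTTTTAAAAAAAV
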