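>TM synthetic mt-tRNA cloverleaf (designed fixture)
GCCTGGTAGCGGTTTAATCCGCGCGGACAGTACTCGTCCGGTAGGGAGTTACCCTCTCCCACCAGGCA
(((((((.((((......)))).(((((.......)))))...(((((.......)))))))))))).
AAAAAAAVDDDDLLLLLLDDDDVCCCCCLLLLLLLCCCCCVVVTTTTTLLLLLLLTTTTTAAAAAAAV
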