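{
 "transcript_A": {
  "name": "toyA",
  "exons": [
   "ATGGAGGACGG",
   "CGCATATTAT",
   "TTCCCTCGAATTT",
   "TGCGTCCCCATG",
   "CATTCCCAAACGGA",
   "CCAAGGACCG",
   "GGGTAAATCGG",
   "ATTCTGTGGTTGTAA"
  ]
 },
 "transcript_B": {
  "name": "toyB",
  "exons": [
   "ATGGAGGACGG",
   "TGCATATTAT",
   "TTCACTCGAATTT",
   "TGAGTCCCCATA",
   "CATTCCCACACGGA",
   "CCAAGGCCCG",
   "GGGTACATCGG",
   "ATTATGTGGTTGTAA"
  ]
 }
}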