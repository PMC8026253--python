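{
 "comment": "synthetic regression fixture: summary triplet of 5000 trials simulated at capacity 10, decay 2, utility 0.9 (vector engine, seed 123)",
 "params": [
  10,
  2,
  0.9
 ],
 "n_trials": 5000,
 "seed": 123,
 "revisit_by_position": [
  0.0,
  0.0,
  0.0007334328066989218,
  0.001622105082026315,
  0.002433288330147137,
  0.002791636840942843,
  0.0038232603889117437,
  0.004219561261763097,
  0.004886883974949653,
  0.005784652020708136,
  0.006747151160492073,
  0.021417824828483048,
  0.03355400269578698,
  0.047237962643385145,
  0.05874133262818271,
  0.06712797202821924,
  0.0705109956946664,
  0.07273670971129301,
  0.07597345181477828,
  0.07638524938829619,
  0.08143554199294202,
  0.08909336518038256,
  0.08695355066879533,
  0.09216357746506612,
  0.09362649139308304
 ],
 "revisit_by_distance": [
  0.0,
  0.05644615037254459,
  0.04718898171144728,
  0.033641905622036575,
  0.035448182433958,
  0.027997290584782116,
  0.0219011063445473,
  0.02483630616391962,
  0.017385414314743733,
  0.13389026868367576,
  0.16662903589975164,
  0.13637389930006774,
  0.11131180853465794,
  0.06615488823662226,
  0.04335064348611425,
  0.03386769022352676,
  0.02099796793858659,
  0.009482953262587492,
  0.005193045834274102,
  0.004515692029803568,
  0.002257846014901784,
  0.0006773538044705351,
  0.0004515692029803567,
  0.0,
  0.0
 ],
 "saccade_count_dist": [
  0.0658,
  0.0704,
  0.0692,
  0.0584,
  0.0632,
  0.0616,
  0.0626,
  0.066,
  0.0636,
  0.0598,
  0.0636,
  0.0536,
  0.0438,
  0.0422,
  0.027,
  0.022,
  0.0204,
  0.0152,
  0.0144,
  0.0124,
  0.009,
  0.0054,
  0.0048,
  0.0032,
  0.0224
 ]
}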