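# Built-in polarized basis (6-31G** contractions: split valence + d on
# heavy atoms, p on hydrogen)
basis
H S
     18.73113700             0.03349460
      2.82539370             0.23472695
      0.64012170             0.81375733
H S
      0.16127780             1.00000000
H P
      1.10000000             1.00000000
O S
   5484.67170000             0.00183110
    825.23495000             0.01395010
    188.04696000             0.06844510
     52.96450000             0.23271430
     16.89757000             0.47019300
      5.79963530             0.35852090
O SP
     15.53961600            -0.11077750             0.07087430
      3.59993360            -0.14802630             0.33975280
      1.01376180             1.13076700             0.72715860
O SP
      0.27000580             1.00000000             1.00000000
O D
      0.80000000             1.00000000
F S
   7001.71309000             0.00181962
   1051.36609000             0.01391608
    239.28569000             0.06840532
     64.25146400             0.23318576
     18.46975300             0.47126744
      6.23024860             0.35661855
F SP
     22.69765700            -0.10850698             0.07162872
      4.98723390            -0.14645166             0.34591210
      1.34916130             1.12868858             0.72246996
F SP
      0.31228550             1.00000000             1.00000000
F D
      0.80000000             1.00000000
end
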