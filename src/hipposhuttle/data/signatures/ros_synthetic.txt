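# SYNTHETIC placeholder signature gene list (one gene per line).
# Replace with the published ROS signature for real analyses.
ROS_g00
ROS_g01
ROS_g02
ROS_g03
ROS_g04
ROS_g05
ROS_g06
ROS_g07
ROS_g08
ROS_g09
ROS_g10
ROS_g11
ROS_g12
ROS_g13
ROS_g14
ROS_g15
ROS_g16
ROS_g17
ROS_g18
ROS_g19
ROS_g20
ROS_g21
ROS_g22
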